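import numpy as np
import pandas as pd
import pytest

from levantadmix.data import Dataset, make_ind_table, make_snp_table


def random_dataset(rng: np.random.Generator, n_ind: int = 20, n_snps: int = 50,
                   missing_rate: float = 0.1, n_pops: int = 2) -> Dataset:
    """A random valid diploid dataset with some missing calls."""
    # strand-unambiguous allele pairs only, so merges keep every SNP
    pairs = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")])
    pick = rng.choice(4, size=n_snps)
    aa_b = pairs[pick]
    gpos = np.sort(rng.uniform(0, 2.0, size=n_snps))
    snps = make_snp_table(
        chrom=np.ones(n_snps, dtype=int),
        physical_pos=np.round(gpos * 1e8).astype(np.int64) + np.arange(n_snps),
        genetic_pos=gpos,
        allele_a=aa_b[:, 0],
        allele_b=aa_b[:, 1],
    )
    pops = [f"pop{i % n_pops}" for i in range(n_ind)]
    inds = make_ind_table([f"ind{i}" for i in range(n_ind)], pops)
    geno = rng.integers(0, 3, size=(n_ind, n_snps)).astype(np.int8)
    geno[rng.random(geno.shape) < missing_rate] = -1
    return Dataset(snps, inds, geno)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)


def freq_dataset(freq_by_pop: dict, n_ind: int, seed: int) -> Dataset:
    """Binomial genotype panel from per-population frequency arrays."""
    from levantadmix.data import AlleleFrequencySet
    from levantadmix.simgraph import sample_genotypes

    sets = {
        k: AlleleFrequencySet(np.asarray(v, dtype=float), np.full(len(v), np.inf))
        for k, v in freq_by_pop.items()
    }
    return sample_genotypes(sets, n_ind=n_ind, seed=seed)
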