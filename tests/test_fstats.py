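"""f-statistics: exact identities, oracle agreement, jackknife behavior."""

import numpy as np
import pytest

from levantadmix.data import Dataset, make_ind_table, make_snp_table
from levantadmix.fstats import (
    BlockPartition,
    f2,
    f2_from_freqs,
    f3,
    f3_from_freqs,
    f4,
    f4_from_freqs,
    f4_scan,
    make_blocks,
    pop_frequencies,
)

from conftest import freq_dataset, random_dataset


def uniform_blocks(n_snps: int, n_blocks: int) -> BlockPartition:
    idx = (np.arange(n_snps) * n_blocks) // n_snps
    return BlockPartition(index=idx, n_blocks=n_blocks)


def snp_map(chrom_cm: list[float], per_cm: int = 10):
    chroms, gpos = [], []
    for c, length in enumerate(chrom_cm):
        k = int(length * per_cm)
        g = np.arange(k) / per_cm / 100.0  # Morgans, spans [0, length cM)
        chroms.extend([str(c + 1)] * k)
        gpos.extend(g)
    gpos = np.asarray(gpos)
    return make_snp_table(
        chrom=np.asarray(chroms),
        physical_pos=(gpos * 1e8).astype(np.int64) + np.tile(np.arange(len(gpos)), 1),
        genetic_pos=gpos,
    )


class TestMakeBlocks:
    def test_single_chromosome_count(self):
        blocks = make_blocks(snp_map([10.0]), block_cm=5.0)
        assert blocks.n_blocks == 2

    def test_blocks_never_span_chromosomes(self):
        snps = snp_map([7.0, 7.0])
        blocks = make_blocks(snps, block_cm=5.0)
        chrom = snps["chrom"].to_numpy()
        for b in range(blocks.n_blocks):
            assert len(set(chrom[blocks.index == b])) == 1

    def test_genome_wide_count(self):
        blocks = make_blocks(snp_map([35.0] * 22), block_cm=5.0)
        assert blocks.n_blocks == 154

    def test_empty_table_errors(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            make_blocks(snp_map([1.0]).iloc[:0])


class TestPopFrequencies:
    def test_pseudo_haploid_and_masking(self):
        snps = snp_map([1.0])[:3]
        inds = make_ind_table(["a", "b", "c"], ["P", "P", "Q"])
        geno = np.array([[2, -1, 0], [0, -1, 1], [1, -1, 2]], dtype=np.int8)
        ds = Dataset(snps, inds, geno)
        fr = pop_frequencies(ds, ["P", "Q"])
        assert fr["P"].freq[0] == 0.5  # {2,0}/4 alleles
        assert np.isnan(fr["P"].freq[1])  # all missing -> masked
        assert fr["Q"].freq[2] == 1.0

    def test_mixed_genotypes(self):
        snps = snp_map([1.0])[:1]
        ds = Dataset(snps, make_ind_table(["a", "b", "c"], ["P"] * 3),
                     np.array([[0], [1], [2]], dtype=np.int8))
        assert pop_frequencies(ds, ["P"])["P"].freq[0] == 0.5

    def test_unknown_label(self, small_dataset):
        with pytest.raises(KeyError):
            pop_frequencies(small_dataset, ["nope"])


class TestFStatIdentities:
    def test_f4_duplicate_pair_is_zero(self, rng):
        ds = random_dataset(rng, n_ind=12, n_snps=60, n_pops=4)
        blocks = make_blocks(ds.snps)
        r = f4(ds, "pop0", "pop0", "pop1", "pop2", blocks)
        assert r.estimate == 0.0 and r.z == 0.0

    def test_f4_antisymmetry_and_pair_swap(self, rng):
        ds = random_dataset(rng, n_ind=12, n_snps=60, n_pops=4, missing_rate=0)
        blocks = make_blocks(ds.snps)
        a = f4(ds, "pop0", "pop1", "pop2", "pop3", blocks)
        b = f4(ds, "pop1", "pop0", "pop2", "pop3", blocks)
        c = f4(ds, "pop2", "pop3", "pop0", "pop1", blocks)
        assert a.estimate == pytest.approx(-b.estimate, abs=1e-15)
        assert a.estimate == pytest.approx(c.estimate, abs=1e-15)
        assert a.se == pytest.approx(b.se, abs=1e-15)

    def test_f4_toy_value(self):
        blocks = uniform_blocks(3, 3)
        r = f4_from_freqs(
            np.array([1, 0, 0.5]), np.array([0, 0, 0.5]),
            np.array([1, 1, 0.0]), np.array([0, 1, 0.0]), blocks,
        )
        assert r.estimate == pytest.approx(1 / 3, abs=1e-15)

    def test_f3_toy_value_and_symmetry(self):
        blocks = uniform_blocks(2, 2)
        r = f3_from_freqs(np.array([0.5, 0.5]), np.array([1.0, 0.0]),
                          np.array([0.0, 1.0]), blocks)
        assert r.estimate == pytest.approx(-0.25, abs=1e-15)
        s = f3_from_freqs(np.array([0.5, 0.5]), np.array([0.0, 1.0]),
                          np.array([1.0, 0.0]), blocks)
        assert s.estimate == r.estimate

    def test_f3_target_equals_source_is_zero(self, rng):
        ds = random_dataset(rng, n_ind=12, n_snps=40, n_pops=2)
        r = f3(ds, "pop0", "pop0", "pop1", make_blocks(ds.snps))
        assert r.estimate == 0.0

    def test_f2_toy_identity_symmetry(self):
        blocks = uniform_blocks(2, 2)
        r = f2_from_freqs(np.array([1.0, 0.0]), np.array([0.0, 0.0]), blocks)
        assert r.estimate == pytest.approx(0.5, abs=1e-15)
        same = f2_from_freqs(np.array([0.3, 0.7]), np.array([0.3, 0.7]), blocks)
        assert same.estimate == 0.0

    def test_f4_additivity(self):
        rng = np.random.default_rng(5)
        p = {k: rng.uniform(0, 1, 30) for k in "ABCDE"}
        blocks = uniform_blocks(30, 5)
        f_cd = f4_from_freqs(p["A"], p["B"], p["C"], p["D"], blocks).estimate
        f_de = f4_from_freqs(p["A"], p["B"], p["D"], p["E"], blocks).estimate
        f_ce = f4_from_freqs(p["A"], p["B"], p["C"], p["E"], blocks).estimate
        assert f_cd + f_de == pytest.approx(f_ce, abs=1e-14)

    def test_global_allele_flip_invariance(self, rng):
        ds = random_dataset(rng, n_ind=16, n_snps=80, n_pops=4)
        flipped_geno = ds.geno.copy()
        nm = flipped_geno >= 0
        flipped_geno[nm] = 2 - flipped_geno[nm]
        flipped = Dataset(ds.snps.copy(), ds.inds.copy(), flipped_geno)
        blocks = make_blocks(ds.snps)
        for fn, pops in [(f4, ("pop0", "pop1", "pop2", "pop3")),
                         (f3, ("pop0", "pop1", "pop2")),
                         (f2, ("pop0", "pop1"))]:
            a = fn(ds, *pops, blocks)
            b = fn(flipped, *pops, blocks)
            assert a.estimate == pytest.approx(b.estimate, abs=1e-14)
            assert a.se == pytest.approx(b.se, abs=1e-14)


class TestOracleEquivalence:
    def test_direct_summation_oracle(self):
        """f2/f3/f4 equal their direct per-SNP summation on random tables."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            pA, pB, pC, pD = (rng.uniform(0, 1, n) for _ in range(4))
            blocks = uniform_blocks(n, max(2, n // 7))
            assert f4_from_freqs(pA, pB, pC, pD, blocks).estimate == pytest.approx(
                np.mean((pA - pB) * (pC - pD)), abs=1e-12)
            assert f3_from_freqs(pA, pB, pC, blocks).estimate == pytest.approx(
                np.mean((pA - pB) * (pA - pC)), abs=1e-12)
            assert f2_from_freqs(pA, pB, blocks).estimate == pytest.approx(
                np.mean((pA - pB) ** 2), abs=1e-12)


class TestF4Scan:
    def test_single_candidate_matches_direct(self, rng):
        ds = random_dataset(rng, n_ind=16, n_snps=60, n_pops=4, missing_rate=0)
        blocks = make_blocks(ds.snps)
        table = f4_scan(ds, ("pop0", "pop2", "pop3"), ["pop1"], blocks)
        direct = f4(ds, "pop0", "pop1", "pop2", "pop3", blocks)
        assert table.loc[0, "estimate"] == pytest.approx(direct.estimate)
        assert table.loc[0, "z"] == pytest.approx(direct.z)

    def test_candidate_equal_fixed_pop_is_zero(self, rng):
        ds = random_dataset(rng, n_ind=16, n_snps=60, n_pops=3)
        blocks = make_blocks(ds.snps)
        table = f4_scan(ds, ("pop0", "pop1", "pop2"), ["pop0"], blocks)
        assert table.loc[0, "z"] == 0.0

    def test_drift_sharing_candidate_most_negative(self):
        """A candidate sharing drift with C draws the most negative Z."""
        from levantadmix.simgraph import DemographyGraph, sample_genotypes, simulate_graph_frequencies

        nodes = ["Root", "A", "B", "C", "X", "N1", "N2", "anc"]
        edges = {"A": ("Root", 0.02), "B": ("Root", 0.02), "anc": ("Root", 0.01),
                 "C": ("anc", 0.02), "X": ("anc", 0.02),
                 "N1": ("Root", 0.02), "N2": ("Root", 0.02)}
        graph = DemographyGraph(nodes=nodes, edges=edges)
        hits = 0
        for rep in range(20):
            freqs = simulate_graph_frequencies(graph, n_snps=4000, seed=1000 + rep)
            ds = sample_genotypes({k: freqs[k] for k in ["A", "B", "C", "X", "N1", "N2"]},
                                  n_ind=10, seed=2000 + rep)
            blocks = make_blocks(ds.snps)
            # f4(A, cand; C, B): cand sharing drift with C -> negative
            table = f4_scan(ds, ("A", "C", "B"), ["X", "N1", "N2"], blocks)
            if table.loc[0, "candidate"] == "X":
                hits += 1
        assert hits >= 18  # >= 90% of 20 replicates


class TestFStatProperties:
    """Algebraic identities over arbitrary frequency tables."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    freq_arrays = hnp.arrays(
        float, st.integers(min_value=6, max_value=40).map(lambda n: (5, n)),
        elements=st.floats(0, 1, allow_nan=False),
    )

    @given(freq_arrays)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_identities_hold(self, freqs):
        pA, pB, pC, pD, pE = freqs
        blocks = uniform_blocks(freqs.shape[1], max(2, freqs.shape[1] // 5))
        f_ab = f4_from_freqs(pA, pB, pC, pD, blocks)
        f_ba = f4_from_freqs(pB, pA, pC, pD, blocks)
        assert f_ab.estimate == pytest.approx(-f_ba.estimate, abs=1e-13)
        # pair-swap symmetry
        f_sw = f4_from_freqs(pC, pD, pA, pB, blocks)
        assert f_ab.estimate == pytest.approx(f_sw.estimate, abs=1e-13)
        # additivity over the third slot
        f_de = f4_from_freqs(pA, pB, pD, pE, blocks)
        f_ce = f4_from_freqs(pA, pB, pC, pE, blocks)
        assert f_ab.estimate + f_de.estimate == pytest.approx(f_ce.estimate, abs=1e-12)
        # global allele-label flip leaves every statistic unchanged
        q = [1 - p for p in (pA, pB, pC, pD)]
        f_fl = f4_from_freqs(*q, blocks)
        assert f_ab.estimate == pytest.approx(f_fl.estimate, abs=1e-13)
        assert f2_from_freqs(pA, pA, blocks).estimate == 0.0


def test_jackknife_se_matches_empirical_sd():
    """Block-jackknife SE is calibrated on homogeneous data (factor 0.7-1.3)."""
    from levantadmix.simgraph import DemographyGraph, sample_genotypes, simulate_graph_frequencies

    nodes = ["Root", "A", "B", "C", "D"]
    edges = {k: ("Root", 0.02) for k in "ABCD"}
    graph = DemographyGraph(nodes=nodes, edges=edges)
    ests, ses = [], []
    for rep in range(60):
        freqs = simulate_graph_frequencies(graph, n_snps=3000, seed=500 + rep)
        ds = sample_genotypes({k: freqs[k] for k in "ABCD"}, n_ind=10, seed=700 + rep)
        r = f4(ds, "A", "B", "C", "D", make_blocks(ds.snps))
        ests.append(r.estimate)
        ses.append(r.se)
    ratio = np.mean(ses) / np.std(ests, ddof=1)
    assert 0.7 < ratio < 1.3
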