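"""In-memory genotype data model: SNP table, individuals, genotype matrix.

Genotypes count copies of ``allele_a`` (the first allele column of the SNP
table): 0, 1 or 2, with :data:`MISSING` (-1) for no call.  Pseudo-haploid
samples — low-coverage ancient genomes represented by a single randomly
drawn allele per site — carry only {0, 2, MISSING}.  Every downstream
statistic applies its own per-SNP complete-case rule; nothing here imputes.

Physical positions are 1-based; genetic positions are in Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the int8 genotype matrix.
MISSING: int = -1

SNP_COLUMNS = ["snp_id", "chrom", "genetic_pos", "physical_pos", "allele_a", "allele_b"]
IND_COLUMNS = ["ind_id", "sex", "population"]

# Strand-ambiguous allele pairs: indistinguishable from their own
# reverse-complement, so they cannot be reconciled across panels whose
# strand conventions are unknown.
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class Dataset:
    """A genotype panel: SNP metadata, individual metadata and the matrix.

    Parameters
    ----------
    snps
        DataFrame with columns ``snp_id, chrom, genetic_pos, physical_pos,
        allele_a, allele_b``, sorted by (chrom, physical_pos) with
        non-decreasing genetic positions within each chromosome.
    inds
        DataFrame with columns ``ind_id, sex, population``; ``ind_id`` unique.
    geno
        int8 array of shape (n_individuals, n_snps), entries in
        {0, 1, 2, MISSING}, counting copies of ``allele_a``.
    """

    snps: pd.DataFrame
    inds: pd.DataFrame
    geno: np.ndarray
    #: optional phased haplotypes (2*n_ind, n_snps) from the mosaic simulator
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.inds = self.inds.reset_index(drop=True)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        """Check internal consistency; raise ``ValueError`` on violation."""
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table lacks columns {missing_cols}")
        missing_cols = [c for c in IND_COLUMNS if c not in self.inds.columns]
        if missing_cols:
            raise ValueError(f"inds table lacks columns {missing_cols}")
        if self.geno.shape != (len(self.inds), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.geno.shape} does not match "
                f"{len(self.inds)} individuals x {len(self.snps)} SNPs"
            )
        if self.inds["ind_id"].duplicated().any():
            dup = self.inds.loc[self.inds["ind_id"].duplicated(), "ind_id"].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        valid = np.isin(self.geno, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.geno[~valid].ravel()[0]
            raise ValueError(f"genotype value {bad} outside {{0,1,2,{MISSING}}}")
        if len(self.snps):
            if (self.snps["allele_a"] == self.snps["allele_b"]).any():
                raise ValueError("allele_a == allele_b at some SNP")
            if (self.snps["genetic_pos"] < 0).any():
                raise ValueError("negative genetic position")
            for _, grp in self.snps.groupby("chrom", sort=False):
                if not grp["physical_pos"].is_monotonic_increasing:
                    raise ValueError("SNPs not sorted by physical position within chromosome")
                if not grp["genetic_pos"].is_monotonic_increasing:
                    raise ValueError("genetic positions decrease within chromosome")

    # -- basic accessors --------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_inds(self) -> int:
        return len(self.inds)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.inds["population"]))

    def ind_indices(self, population: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``population``."""
        idx = np.flatnonzero(self.inds["population"].to_numpy() == population)
        if idx.size == 0:
            raise KeyError(f"unknown population label {population!r}")
        return idx

    def subset_snps(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask)
        hap = self.haplotypes[:, mask] if self.haplotypes is not None else None
        return Dataset(self.snps.loc[mask], self.inds.copy(), self.geno[:, mask], hap)

    def copy_population(self, population: str, new_label: str) -> "Dataset":
        """Return a dataset with the individuals of one population duplicated
        under a new label (ids suffixed), e.g. to test self-consistency."""
        idx = self.ind_indices(population)
        dup = self.inds.iloc[idx].copy()
        dup["ind_id"] = dup["ind_id"] + "_copy"
        dup["population"] = new_label
        inds = pd.concat([self.inds, dup], ignore_index=True)
        geno = np.concatenate([self.geno, self.geno[idx]], axis=0)
        return Dataset(self.snps.copy(), inds, geno)


@dataclass
class AlleleFrequencySet:
    """Per-SNP frequencies of ``allele_a`` for one population.

    ``freq`` is NaN where the frequency is undefined (no calls, or
    uninformative likelihoods); ``n`` is the number of allele observations
    (calls * ploidy for genotype data, individuals for likelihood data)
    behind each estimate.
    """

    freq: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n = np.asarray(self.n)
        if self.freq.shape != self.n.shape:
            raise ValueError("freq and n must have identical shape")
        ok = np.isnan(self.freq) | ((self.freq >= 0) & (self.freq <= 1))
        if not ok.all():
            raise ValueError("frequencies outside [0, 1]")

    def __len__(self) -> int:
        return self.freq.size


def make_snp_table(
    chrom: np.ndarray,
    physical_pos: np.ndarray,
    genetic_pos: np.ndarray,
    allele_a=None,
    allele_b=None,
    snp_id=None,
) -> pd.DataFrame:
    """Assemble a SNP table from arrays, defaulting alleles to A/G."""
    n = len(physical_pos)
    df = pd.DataFrame(
        {
            "snp_id": snp_id if snp_id is not None else [f"snp{i}" for i in range(n)],
            "chrom": np.asarray(chrom).astype(str),
            "genetic_pos": np.asarray(genetic_pos, dtype=float),
            "physical_pos": np.asarray(physical_pos, dtype=np.int64),
            "allele_a": allele_a if allele_a is not None else ["A"] * n,
            "allele_b": allele_b if allele_b is not None else ["G"] * n,
        }
    )
    return df


def make_ind_table(ind_ids, populations, sex=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ind_id": list(ind_ids),
            "sex": list(sex) if sex is not None else ["U"] * len(ind_ids),
            "population": list(populations),
        }
    )


def pseudo_haploidize(ds: Dataset, seed: int) -> Dataset:
    """Replace each diploid genotype by a single randomly drawn allele.

    Homozygotes are unchanged (0 -> 0, 2 -> 2); heterozygotes become 0 or 2
    with probability 1/2 each, mimicking the representation of low-coverage
    ancient samples by one random sequence per site.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    geno = ds.geno.copy()
    het = geno == 1
    geno[het] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(het.sum()))
    return Dataset(ds.snps.copy(), ds.inds.copy(), geno)


def intersect_datasets(a: Dataset, b: Dataset) -> Dataset:
    """Merge two panels on shared SNPs, reconciling allele encodings.

    SNPs are matched on (chrom, physical_pos).  At each shared site the
    allele pairs are reconciled: identical pairs pass through, swapped
    pairs recode b's genotypes g -> 2 - g, and strand flips are resolved
    by complementing b's alleles first.  Strand-ambiguous A/T and C/G
    sites and sites with irreconcilable alleles are dropped (counts
    recorded on the result as ``merge_log``).  Individuals are the union
    (ids must not collide).
    """
    a_key = pd.MultiIndex.from_frame(a.snps[["chrom", "physical_pos"]])
    b_key = pd.MultiIndex.from_frame(b.snps[["chrom", "physical_pos"]])
    b_lookup = {k: i for i, k in enumerate(b_key)}

    keep_a: list[int] = []
    keep_b: list[int] = []
    flip_b: list[bool] = []
    n_ambiguous = 0
    n_mismatch = 0
    for ia, key in enumerate(a_key):
        ib = b_lookup.get(key)
        if ib is None:
            continue
        aa, ab = a.snps["allele_a"].iat[ia], a.snps["allele_b"].iat[ia]
        ba, bb = b.snps["allele_a"].iat[ib], b.snps["allele_b"].iat[ib]
        if (aa, ab) in _AMBIGUOUS_PAIRS or (ba, bb) in _AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        if (ba, bb) == (aa, ab):
            flip = False
        elif (ba, bb) == (ab, aa):
            flip = True
        else:
            ca = _COMPLEMENT.get(ba)
            cb = _COMPLEMENT.get(bb)
            if (ca, cb) == (aa, ab):
                flip = False
            elif (ca, cb) == (ab, aa):
                flip = True
            else:
                n_mismatch += 1
                continue
        keep_a.append(ia)
        keep_b.append(ib)
        flip_b.append(flip)

    if not keep_a:
        raise ValueError("no overlapping SNPs between datasets after allele reconciliation")

    snps = a.snps.iloc[keep_a].reset_index(drop=True)
    geno_a = a.geno[:, keep_a]
    geno_b = b.geno[:, keep_b].copy()
    flip_arr = np.asarray(flip_b)
    if flip_arr.any():
        cols = geno_b[:, flip_arr]
        nonmiss = cols != MISSING
        cols[nonmiss] = 2 - cols[nonmiss]
        geno_b[:, flip_arr] = cols

    shared_ids = set(a.inds["ind_id"]) & set(b.inds["ind_id"])
    if shared_ids:
        raise ValueError(f"individual ids present in both datasets: {sorted(shared_ids)[:5]}")
    inds = pd.concat([a.inds, b.inds], ignore_index=True)
    merged = Dataset(snps, inds, np.concatenate([geno_a, geno_b], axis=0))
    merged.merge_log = {  # type: ignore[attr-defined]
        "n_shared": len(keep_a),
        "n_flipped": int(flip_arr.sum()),
        "n_ambiguous_dropped": n_ambiguous,
        "n_allele_mismatch_dropped": n_mismatch,
        "n_private_a": a.n_snps - len(keep_a) - n_ambiguous - n_mismatch,
        "n_private_b": b.n_snps - len(keep_b) - n_ambiguous - n_mismatch,
    }
    return merged
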