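"""f2/f3/f4 statistics with weighted block-jackknife standard errors.

The f-statistics are moments of population allele-frequency differences:

    f2(A, B)       = mean_i (pA - pB)^2
    f3(T; A, B)    = mean_i (pT - pA)(pT - pB)
    f4(A, B; C, D) = mean_i (pA - pB)(pC - pD)

estimated from sample frequencies, averaging over the SNPs where every
involved population has at least one call (per-statistic complete-case
masking, which keeps low-coverage ancient samples usable without forcing
a global SNP intersection).

Standard errors use the weighted block jackknife: contiguous genetic-map
blocks (default 5 cM, beyond the range of background LD) are deleted one
at a time and the estimate recomputed; blocks are weighted by their
retained SNP counts, which vary strongly under aDNA missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from levantadmix.data import AlleleFrequencySet, Dataset


@dataclass
class BlockPartition:
    """Assignment of SNPs to contiguous jackknife blocks.

    ``index`` gives each SNP's block id in [0, n_blocks); blocks never
    span chromosomes.
    """

    index: np.ndarray
    n_blocks: int
    bounds: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=np.int64)
        if len(self.index) and (self.index.min() < 0 or self.index.max() >= self.n_blocks):
            raise ValueError("block index out of range")


def make_blocks(snps: pd.DataFrame, block_cm: float = 5.0) -> BlockPartition:
    """Partition a sorted SNP table into contiguous blocks of ``block_cm``.

    Blocks are laid down greedily from each chromosome's first SNP;
    trailing short blocks are kept.  Raises on an empty table.
    """
    if len(snps) == 0:
        raise ValueError("empty SNP table")
    snps = snps.reset_index(drop=True)
    width = block_cm / 100.0  # Morgans
    index = np.empty(len(snps), dtype=np.int64)
    bounds_rows = []
    offset = 0
    for chrom, grp in snps.groupby("chrom", sort=False):
        g = grp["genetic_pos"].to_numpy()
        local = np.floor((g - g[0]) / width).astype(np.int64)
        index[grp.index.to_numpy()] = local + offset
        for b in range(local.max() + 1):
            bounds_rows.append(
                {
                    "block": offset + b,
                    "chrom": chrom,
                    "start_morgan": g[0] + b * width,
                    "end_morgan": g[0] + (b + 1) * width,
                    "n_snps": int((local == b).sum()),
                }
            )
        offset += local.max() + 1
    return BlockPartition(index=index, n_blocks=offset, bounds=pd.DataFrame(bounds_rows))


def pop_frequencies(ds: Dataset, pops: Sequence[str]) -> dict[str, AlleleFrequencySet]:
    """Sample allele frequencies (allele_a dosage / 2) per population.

    Returns one :class:`AlleleFrequencySet` per label; SNPs with zero
    calls in a population get frequency NaN and n = 0.  ``n`` counts
    allele observations (2 per called diploid genotype).
    """
    out: dict[str, AlleleFrequencySet] = {}
    for pop in pops:
        rows = ds.ind_indices(pop)
        g = ds.geno[rows].astype(np.float64)
        called = g >= 0
        n_calls = called.sum(axis=0)
        dose = np.where(called, g, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_calls > 0, dose / (2.0 * n_calls), np.nan)
        out[pop] = AlleleFrequencySet(freq=freq, n=2 * n_calls)
    return out


@dataclass
class FStatResult:
    """An f-statistic estimate with weighted block-jackknife uncertainty."""

    stat: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    loo: np.ndarray = field(repr=False)  # leave-one-block-out estimates
    block_weights: np.ndarray = field(repr=False)  # retained SNPs per block

    def to_dict(self) -> dict:
        return {
            "stat": self.stat,
            "pops": ",".join(self.pops),
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "n_snps": self.n_snps,
            "n_blocks": self.n_blocks,
        }


def block_sums(values: np.ndarray, mask: np.ndarray, blocks: BlockPartition):
    """Per-block sums and retained-SNP counts of a per-SNP statistic."""
    v = np.where(mask, values, 0.0)
    sums = np.bincount(blocks.index, weights=v, minlength=blocks.n_blocks)
    counts = np.bincount(blocks.index, weights=mask.astype(float), minlength=blocks.n_blocks)
    return sums, counts


def weighted_jackknife(sums: np.ndarray, counts: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Weighted delete-one-block jackknife of a ratio-of-sums mean.

    ``sums``/``counts`` are per-block statistic sums and SNP counts; empty
    blocks are dropped.  Returns (estimate, se, leave-one-out estimates,
    block weights).  Uses the weighted jackknife variance of Busing et
    al., with block SNP counts as weights.
    """
    keep = counts > 0
    sums, counts = sums[keep], counts[keep]
    g = len(sums)
    n = counts.sum()
    if g < 2:
        raise ValueError(f"only {g} non-empty block(s); need >= 2")
    total = sums.sum()
    est = total / n
    loo = (total - sums) / (n - counts)
    h = n / counts
    theta_j = g * est - ((1.0 - counts / n) * loo).sum()
    tau = est * h - loo * (h - 1.0)
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return float(est), float(np.sqrt(max(var, 0.0))), loo, counts


def _fstat(
    name: str,
    pops: tuple[str, ...],
    freqs: Sequence[np.ndarray],
    per_snp: Callable[..., np.ndarray],
    blocks: BlockPartition,
) -> FStatResult:
    mask = np.ones(len(freqs[0]), dtype=bool)
    for f in freqs:
        mask &= ~np.isnan(f)
    if mask.sum() == 0:
        raise ValueError(f"{name}{pops}: no SNPs with complete data")
    values = per_snp(*(np.nan_to_num(f) for f in freqs))
    sums, counts = block_sums(values, mask, blocks)
    est, se, loo, w = weighted_jackknife(sums, counts)
    z = est / se if se > 0 else 0.0
    return FStatResult(
        stat=name,
        pops=pops,
        estimate=est,
        se=se,
        z=z,
        n_snps=int(mask.sum()),
        n_blocks=len(w),
        loo=loo,
        block_weights=w,
    )


def f4_from_freqs(pA, pB, pC, pD, blocks: BlockPartition, pops=("A", "B", "C", "D")) -> FStatResult:
    """f4 from frequency arrays (NaN = missing): mean (pA-pB)(pC-pD)."""
    return _fstat("f4", tuple(pops), (pA, pB, pC, pD), lambda a, b, c, d: (a - b) * (c - d), blocks)


def f3_from_freqs(pT, pA, pB, blocks: BlockPartition, pops=("T", "A", "B")) -> FStatResult:
    return _fstat("f3", tuple(pops), (pT, pA, pB), lambda t, a, b: (t - a) * (t - b), blocks)


def f2_from_freqs(pA, pB, blocks: BlockPartition, pops=("A", "B")) -> FStatResult:
    return _fstat("f2", tuple(pops), (pA, pB), lambda a, b: (a - b) ** 2, blocks)


def f4(ds: Dataset, A: str, B: str, C: str, D: str, blocks: BlockPartition) -> FStatResult:
    """f4(A, B; C, D) with weighted block-jackknife SE.

    Plain (unnormalized) f4 — the covariance of allele-frequency
    differences — not the heterozygosity-normalized D-statistic; see
    :func:`d_stat` for the normalized variant.
    """
    fr = pop_frequencies(ds, _unique((A, B, C, D)))
    return f4_from_freqs(fr[A].freq, fr[B].freq, fr[C].freq, fr[D].freq, blocks, pops=(A, B, C, D))


def d_stat(ds: Dataset, A: str, B: str, C: str, D: str, blocks: BlockPartition) -> FStatResult:
    """D-statistic: f4 normalized per SNP set by sum (pA+pB-2pApB)(pC+pD-2pCpD)."""
    fr = pop_frequencies(ds, _unique((A, B, C, D)))
    pA, pB, pC, pD = (fr[x].freq for x in (A, B, C, D))
    mask = ~(np.isnan(pA) | np.isnan(pB) | np.isnan(pC) | np.isnan(pD))
    if mask.sum() == 0:
        raise ValueError("no SNPs with complete data")
    a, b, c, d = (np.nan_to_num(x) for x in (pA, pB, pC, pD))
    num = (a - b) * (c - d)
    den = (a + b - 2 * a * b) * (c + d - 2 * c * d)
    ns, _ = block_sums(num, mask, blocks)
    dsum, counts = block_sums(den, mask, blocks)
    keep = counts > 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 non-empty blocks")
    ns, dsum, counts = ns[keep], dsum[keep], counts[keep]
    gtot = len(ns)
    est = ns.sum() / dsum.sum()
    loo = (ns.sum() - ns) / (dsum.sum() - dsum)
    n = counts.sum()
    h = n / counts
    theta_j = gtot * est - ((1.0 - counts / n) * loo).sum()
    tau = est * h - loo * (h - 1.0)
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / gtot
    se = float(np.sqrt(max(var, 0.0)))
    return FStatResult("D", (A, B, C, D), float(est), se, float(est / se) if se > 0 else 0.0,
                       int(mask.sum()), gtot, loo, counts)


def f3(
    ds: Dataset, target: str, A: str, B: str, blocks: BlockPartition, het_correction: bool = False
) -> FStatResult:
    """f3(target; A, B): negative values indicate the target is admixed
    between populations related to A and B.

    ``het_correction`` subtracts the small-sample bias term
    pT(1-pT)/(nT-1) per SNP (off by default; invalid for pseudo-haploid
    targets, whose apparent heterozygosity is distorted).
    """
    fr = pop_frequencies(ds, _unique((target, A, B)))
    pT, pA, pB = fr[target].freq, fr[A].freq, fr[B].freq
    if not het_correction:
        return f3_from_freqs(pT, pA, pB, blocks, pops=(target, A, B))
    nT = fr[target].n
    mask = ~(np.isnan(pT) | np.isnan(pA) | np.isnan(pB)) & (nT > 1)
    if mask.sum() == 0:
        raise ValueError("no SNPs with complete data and nT > 1")
    t, a, b = (np.nan_to_num(x) for x in (pT, pA, pB))
    corr = np.where(nT > 1, t * (1 - t) / np.maximum(nT - 1, 1), 0.0)
    values = (t - a) * (t - b) - corr
    sums, counts = block_sums(values, mask, blocks)
    est, se, loo, w = weighted_jackknife(sums, counts)
    return FStatResult("f3", (target, A, B), est, se, est / se if se > 0 else 0.0,
                       int(mask.sum()), len(w), loo, w)


def f2(ds: Dataset, A: str, B: str, blocks: BlockPartition) -> FStatResult:
    """f2(A, B): squared frequency distance; the branch-length metric of
    the admixture-graph framework."""
    fr = pop_frequencies(ds, _unique((A, B)))
    return f2_from_freqs(fr[A].freq, fr[B].freq, blocks, pops=(A, B))


def f4_scan(
    ds: Dataset,
    fixed_triple: tuple[str, str, str],
    candidates: Sequence[str],
    blocks: BlockPartition,
    slot: int = 1,
) -> pd.DataFrame:
    """Run f4 with each candidate substituted into one slot of the quartet.

    ``fixed_triple`` fills the other three slots in order; ``slot`` (0-3)
    is the position candidates occupy (default the second population).
    Returns a DataFrame sorted by Z ascending; candidates whose statistic
    is undefined appear as masked rows (NaN estimates).
    """
    if not candidates:
        raise ValueError("no candidate populations")
    rows = []
    for cand in candidates:
        quartet = list(fixed_triple)
        quartet.insert(slot, cand)
        try:
            res = f4(ds, *quartet, blocks)
            rows.append(res.to_dict() | {"candidate": cand})
        except (ValueError, KeyError) as exc:
            rows.append(
                {
                    "stat": "f4",
                    "pops": ",".join(quartet),
                    "candidate": cand,
                    "estimate": np.nan,
                    "se": np.nan,
                    "z": np.nan,
                    "n_snps": 0,
                    "n_blocks": 0,
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values("z", na_position="last").reset_index(drop=True)


def _unique(labels: Sequence[str]) -> list[str]:
    return list(dict.fromkeys(labels))
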