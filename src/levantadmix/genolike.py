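"""Allele-frequency estimation from genotype likelihoods.

Low-coverage samples cannot be genotyped reliably; instead each individual
contributes a likelihood triple GL_i(g) for g in {0, 1, 2} copies of
``allele_a``.  The population allele frequency p maximizes

    L(p) = prod_i sum_g GL_i(g) * Binom(g; 2, p)

which is fitted by EM: posterior genotype weights under the current p,
then p <- (1/2N) sum_i E[g_i | p].  The likelihood is non-decreasing at
every step (standard EM guarantee, asserted in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from levantadmix.data import AlleleFrequencySet

#: binomial coefficients C(2, g) for g = 0, 1, 2
_BINOM2 = np.array([1.0, 2.0, 1.0])


@dataclass
class GenotypeLikelihoods:
    """Likelihood triples per individual per SNP, normalized to max 1.

    ``values`` has shape (n_individuals, n_snps, 3); index g counts copies
    of ``allele_a``.  Triples must be non-negative with at least one
    positive entry.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError("values must have shape (n_ind, n_snp, 3)")
        if (v < 0).any():
            raise ValueError("negative likelihood")
        peaks = v.max(axis=2)
        if (peaks <= 0).any():
            raise ValueError("all-zero likelihood triple")
        self.values = v / peaks[:, :, None]

    @property
    def n_inds(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def genotype_priors(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities Binom(g; 2, p), shape (..., 3)."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def loglik_af(gl: GenotypeLikelihoods, p: np.ndarray) -> np.ndarray:
    """Per-SNP log-likelihood of frequency vector ``p``."""
    mix = np.einsum("isg,sg->is", gl.values, genotype_priors(p))
    return np.log(np.maximum(mix, 1e-300)).sum(axis=0)


def _em_run(v: np.ndarray, p0: float, tol: float, max_iter: int, trace: list | None) -> np.ndarray:
    n_snp = v.shape[1]
    p = np.full(n_snp, p0)
    for _ in range(max_iter):
        prior = genotype_priors(p)  # (n_snp, 3)
        post = v * prior[None, :, :]
        norm = post.sum(axis=2, keepdims=True)
        post = post / np.maximum(norm, 1e-300)
        if trace is not None:
            trace.append(float(np.log(np.maximum(norm[:, :, 0], 1e-300)).sum()))
        e_g = (post * np.arange(3)).sum(axis=2)  # (n_ind, n_snp)
        p_new = e_g.mean(axis=0) / 2.0
        delta = np.max(np.abs(p_new - p)) if n_snp else 0.0
        p = p_new
        if delta < tol:
            break
    return p


def estimate_af_em(
    gl: GenotypeLikelihoods,
    tol: float = 1e-9,
    max_iter: int = 2000,
    return_trace: bool = False,
):
    """Maximum-likelihood allele frequencies per SNP by EM.

    The likelihood in p is usually but not always unimodal (pathological
    likelihood triples can create a second mode), so EM is run from three
    starts (0.05, 0.5, 0.95) and the highest-likelihood solution kept per
    SNP.  SNPs where every individual's triple is flat (uninformative)
    get frequency NaN.  Convergence: max |delta p| < ``tol``, capped at
    ``max_iter`` iterations per start.

    Returns an :class:`AlleleFrequencySet`; with ``return_trace`` also the
    per-iteration total log-likelihood of the central (p0 = 0.5) start
    (monotone non-decreasing by the EM guarantee).
    """
    v = gl.values
    n_ind, n_snp = v.shape[:2]
    # a triple is informative if it distinguishes genotypes at all
    informative = ~np.isclose(v, v[:, :, [0]], rtol=0, atol=1e-12).all(axis=2)
    has_info = informative.any(axis=0)

    trace: list[float] = []
    best_p = None
    best_ll = None
    for p0 in (0.5, 0.05, 0.95):
        p = _em_run(v, p0, tol, max_iter, trace if p0 == 0.5 else None)
        ll = loglik_af(gl, p)
        if best_p is None:
            best_p, best_ll = p, ll
        else:
            better = ll > best_ll
            best_p = np.where(better, p, best_p)
            best_ll = np.where(better, ll, best_ll)

    p = np.where(has_info, best_p, np.nan)
    afs = AlleleFrequencySet(freq=p, n=np.full(n_snp, n_ind))
    if return_trace:
        return afs, np.asarray(trace)
    return afs


def af_correlation(
    a: AlleleFrequencySet, b: AlleleFrequencySet, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Pearson correlation between two frequency sets over shared SNPs.

    Uses SNPs with frequencies present (non-NaN) in both sets; requires at
    least 3.  The confidence interval (default 95%) comes from the Fisher
    z-transform.  Returns ``(r, ci_low, ci_high)``.
    """
    if len(a) != len(b):
        raise ValueError("frequency sets cover different SNP panels")
    mask = ~np.isnan(a.freq) & ~np.isnan(b.freq)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} SNPs shared; need >= 3")
    x, y = a.freq[mask], b.freq[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a frequency vector")
    r = float(np.corrcoef(x, y)[0, 1])
    if n > 3:
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo, hi = -1.0, 1.0
    return r, float(lo), float(hi)
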