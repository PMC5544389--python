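"""Admixture-proportion estimation against outgroup panels, with rank tests.

A target population T is modeled as a mixture of N source populations
S_1..S_N with weights summing to 1, using M outgroup ("right")
populations R_1..R_M (M >= N+1) that are assumed to have received no
gene flow from the left (target/source) side after their divergence.
With R_1 as the base, the model equations are

    f4(T, R_1; R_i, R_1) = sum_j w_j * f4(S_j, R_1; R_i, R_1),  i = 2..M

The left-hand sides form the vector b and the right-hand side f4s the
(M-1) x N matrix A; weights minimize the generalized least squares
criterion (b - Aw)' Sigma^-1 (b - Aw) under sum(w) = 1, where Sigma is
the block-jackknife covariance of b.  Because the constraint makes the
estimator invariant to the additive sampling-variance bias that a shared
base population induces in every f4, no heterozygosity correction is
needed.

The companion rank test asks how many independent ancestry streams
relate the left to the right populations: it tests rank <= r of the
(M-1) x (N+1) matrix of target+source f4 columns via a chi-square on the
covariance-weighted residual of the best rank-r approximation, with
(M-1-r)(N+1-r) degrees of freedom.  A feasible N-source model should
pass the rank-N test; rejection at rank N-1 shows the extra stream is
required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from levantadmix.data import Dataset
from levantadmix.fstats import BlockPartition, block_sums, pop_frequencies

#: ridge factor applied to covariance matrices before inversion
COV_RIDGE = 1e-4


@dataclass
class MixtureModel:
    """Target, ordered sources and ordered rights (rights[0] is the base)."""

    target: str
    sources: list[str]
    rights: list[str]
    allsnps: bool = True

    def __post_init__(self) -> None:
        n, m = len(self.sources), len(self.rights)
        if n < 1:
            raise ValueError("need at least one source")
        if m < n + 1:
            raise ValueError(f"need >= {n + 1} rights for {n} sources, got {m}")
        labels = [self.target, *self.sources, *self.rights]
        if len(set(labels)) != len(labels):
            raise ValueError("target, sources and rights must be disjoint labels")


@dataclass
class F4System:
    """The assembled f4 equation system plus per-block leave-one-out copies.

    ``X`` stacks the target column and source columns: X[:, 0] = b,
    X[:, 1:] = A, shape (M-1, N+1).  ``loo_X`` holds the delete-one-block
    re-estimates, shape (n_blocks, M-1, N+1).
    """

    model: MixtureModel
    X: np.ndarray
    loo_X: np.ndarray = field(repr=False)
    block_weights: np.ndarray = field(repr=False)
    n_snps_per_stat: np.ndarray = field(repr=False)

    @property
    def b(self) -> np.ndarray:
        return self.X[:, 0]

    @property
    def A(self) -> np.ndarray:
        return self.X[:, 1:]

    @property
    def n_blocks(self) -> int:
        return self.loo_X.shape[0]


@dataclass
class MixtureFit:
    """Estimated mixture weights with jackknife uncertainty and model fit."""

    model: MixtureModel
    weights: np.ndarray
    se: np.ndarray
    cov: np.ndarray = field(repr=False)
    rank_p: float
    feasible: bool
    n_snps: int
    loo_weights: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "target": self.model.target,
            "sources": list(self.model.sources),
            "rights": list(self.model.rights),
            "weights": [float(w) for w in self.weights],
            "se": [float(s) for s in self.se],
            "rank_p": float(self.rank_p),
            "feasible": bool(self.feasible),
            "n_snps": int(self.n_snps),
        }


def build_f4_system(ds: Dataset, model: MixtureModel, blocks: BlockPartition) -> F4System:
    """Assemble b, A and their leave-one-block-out copies.

    Under ``allsnps`` each f4 statistic uses its own maximal complete-case
    SNP set; otherwise all statistics share the global intersection of the
    involved populations' coverage.
    """
    lefts = [model.target, *model.sources]
    rights = model.rights
    pops = list(dict.fromkeys(lefts + rights))
    fr = pop_frequencies(ds, pops)
    freq = {p: fr[p].freq for p in pops}

    global_mask = np.ones(ds.n_snps, dtype=bool)
    if not model.allsnps:
        for p in pops:
            global_mask &= ~np.isnan(freq[p])
        if global_mask.sum() == 0:
            raise ValueError("no SNPs covered in every population (allsnps off)")

    r0 = rights[0]
    n_rows, n_cols = len(rights) - 1, len(lefts)
    g = blocks.n_blocks
    sums = np.zeros((g, n_rows, n_cols))
    counts = np.zeros((g, n_rows, n_cols))
    n_snps_per_stat = np.zeros((n_rows, n_cols), dtype=np.int64)
    for i, ri in enumerate(rights[1:]):
        right_term = freq[ri] - freq[r0]
        for j, lj in enumerate(lefts):
            vals = (freq[lj] - freq[r0]) * right_term
            mask = ~np.isnan(vals)
            if not model.allsnps:
                mask &= global_mask
            if mask.sum() == 0:
                raise ValueError(f"f4({lj}, {r0}; {ri}, {r0}) has no SNPs with data")
            s, c = block_sums(vals, mask, blocks)
            sums[:, i, j] = s
            counts[:, i, j] = c
            n_snps_per_stat[i, j] = int(mask.sum())

    tot_sum = sums.sum(axis=0)
    tot_cnt = counts.sum(axis=0)
    X = tot_sum / tot_cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_sum[None] - sums) / (tot_cnt[None] - counts)
    # a block empty for some statistic leaves that entry at the full estimate
    loo = np.where(np.isfinite(loo), loo, X[None])
    block_w = counts.mean(axis=(1, 2))
    keep = block_w > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 jackknife blocks with data")
    return F4System(
        model=model,
        X=X,
        loo_X=loo[keep],
        block_weights=block_w[keep],
        n_snps_per_stat=n_snps_per_stat,
    )


def _jackknife_cov(loo: np.ndarray) -> np.ndarray:
    """Delete-one-block jackknife covariance of a vector estimate.

    ``loo``: (n_blocks, dim) leave-one-out estimates."""
    g = loo.shape[0]
    centered = loo - loo.mean(axis=0)
    return (g - 1) / g * centered.T @ centered


def _ridge(cov: np.ndarray, lam: float = COV_RIDGE) -> np.ndarray:
    scale = np.mean(np.diag(cov))
    if scale <= 0:
        scale = 1e-12
    return cov + lam * scale * np.eye(cov.shape[0])


def _solve_constrained(A: np.ndarray, b: np.ndarray, prec: np.ndarray) -> np.ndarray:
    """Minimize (b - Aw)' prec (b - Aw) subject to sum(w) = 1 (Lagrange)."""
    n = A.shape[1]
    H = A.T @ prec @ A
    c = A.T @ prec @ b
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2.0 * H
    kkt[:n, n] = 1.0
    kkt[n, :n] = 1.0
    rhs = np.concatenate([2.0 * c, [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular mixture system; try larger blocks or fewer right populations"
        ) from exc
    w = sol[:n]
    return w / w.sum()


def fit_proportions(system: F4System) -> MixtureFit:
    """Constrained GLS fit of mixture weights with jackknife SEs.

    The covariance of b is the block-jackknife covariance of its
    leave-one-out copies, ridge-regularized (lambda = 1e-4 of the mean
    diagonal) before inversion; weight SEs come from refitting on every
    leave-one-block system with the covariance held fixed.
    """
    model = system.model
    b, A = system.b, system.A
    sigma = _ridge(_jackknife_cov(system.loo_X[:, :, 0]))
    try:
        prec = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular regularized covariance; try larger blocks or fewer rights"
        ) from exc
    w = _solve_constrained(A, b, prec)

    g = system.n_blocks
    loo_w = np.empty((g, len(w)))
    for j in range(g):
        loo_w[j] = _solve_constrained(system.loo_X[j, :, 1:], system.loo_X[j, :, 0], prec)
    # weighted jackknife variance with block SNP-count weights
    m = system.block_weights
    n = m.sum()
    h = n / m
    theta_j = g * w - ((1.0 - m / n)[:, None] * loo_w).sum(axis=0)
    tau = w[None, :] * h[:, None] - loo_w * (h[:, None] - 1.0)
    dev = tau - theta_j[None, :]
    cov = (dev.T * (1.0 / (h - 1.0))) @ dev / g
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    n_src = len(model.sources)
    rank_p = rank_test(system, r=n_src) if system.X.shape[0] > n_src else float("nan")
    feasible = bool(np.all(w >= -1e-9) and np.all(w <= 1.0 + 1e-9))
    return MixtureFit(
        model=model,
        weights=w,
        se=se,
        cov=cov,
        rank_p=rank_p,
        feasible=feasible,
        n_snps=int(system.n_snps_per_stat.min()),
        loo_weights=loo_w,
    )


def rank_stat(X: np.ndarray, cov_vec: np.ndarray, r: int) -> tuple[float, int]:
    """Chi-square statistic and df for the test rank(X) <= r.

    ``cov_vec`` is the covariance of vec(X) (row-major).  The best rank-r
    approximation under the GLS metric is found by SVD truncation followed
    by alternating generalized-least-squares refinement of the factors.
    """
    p, k = X.shape
    if r < 0 or r > min(p, k):
        raise ValueError(f"rank {r} out of range for {p}x{k} matrix")
    try:
        prec = np.linalg.inv(cov_vec)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance in rank test") from exc

    x = X.ravel()
    if r == 0:
        stat = float(x @ prec @ x)
        return stat, p * k
    if r == min(p, k):
        return 0.0, 0

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Uf = U[:, :r] * s[:r]
    Vf = Vt[:r].T  # (k, r)

    def residual(Um, Vm):
        d = x - (Um @ Vm.T).ravel()
        return float(d @ prec @ d)

    stat = residual(Uf, Vf)
    for _ in range(200):
        # vec(U V') = (I_p kron V) vec(U') ... use explicit design matrices
        # solve for U given V
        D_u = np.kron(np.eye(p), Vf)  # maps vec(U rows) -> vec(X rows)
        lhs = D_u.T @ prec @ D_u
        rhs = D_u.T @ prec @ x
        Uf = np.linalg.lstsq(lhs, rhs, rcond=None)[0].reshape(p, r)
        # solve for V given U
        D_v = np.zeros((p * k, k * r))
        for i in range(p):
            D_v[i * k : (i + 1) * k, :] = np.kron(np.eye(k), Uf[i])
        lhs = D_v.T @ prec @ D_v
        rhs = D_v.T @ prec @ x
        Vf = np.linalg.lstsq(lhs, rhs, rcond=None)[0].reshape(k, r)
        new_stat = residual(Uf, Vf)
        if stat - new_stat < 1e-10 * max(stat, 1.0):
            stat = new_stat
            break
        stat = new_stat
    df = (p - r) * (k - r)
    return max(stat, 0.0), df


def rank_test(system: F4System, r: int) -> float:
    """P-value for rank(X) <= r, X the (M-1) x (N+1) target+source f4 matrix.

    The covariance of vec(X) is estimated by the block jackknife of the
    system's leave-one-out copies, ridge-regularized as elsewhere.  A
    noiseless exactly-rank-r matrix yields statistic 0, p = 1.
    """
    g, p, k = system.loo_X.shape
    loo_vec = system.loo_X.reshape(g, p * k)
    cov = _ridge(_jackknife_cov(loo_vec), lam=max(COV_RIDGE, 1e-12))
    if np.all(np.diag(cov) < 1e-30):
        cov = np.eye(p * k) * 1e-12
    stat, df = rank_stat(system.X, cov, r)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def scan_models(
    ds: Dataset,
    target: str,
    fixed_source: str,
    candidate_sources: Sequence[str],
    rights: Sequence[str],
    blocks: BlockPartition,
    allsnps: bool = True,
    rank_p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fit target = fixed_source + candidate for every candidate and rank.

    Ranking: feasible models first, then models whose rank test does not
    reject (rank_p >= threshold), then smallest SE of the candidate
    weight.  Candidates whose fit fails are kept as masked rows.
    """
    if not candidate_sources:
        raise ValueError("no candidate sources")
    rows = []
    for cand in candidate_sources:
        row: dict = {"candidate": cand}
        try:
            model = MixtureModel(target, [fixed_source, cand], list(rights), allsnps=allsnps)
            fit = fit_proportions(build_f4_system(ds, model, blocks))
            row.update(
                weight_fixed=fit.weights[0],
                weight_candidate=fit.weights[1],
                se_fixed=fit.se[0],
                se_candidate=fit.se[1],
                rank_p=fit.rank_p,
                feasible=fit.feasible,
                n_snps=fit.n_snps,
            )
        except (ValueError, KeyError) as exc:
            row.update(
                weight_fixed=np.nan,
                weight_candidate=np.nan,
                se_fixed=np.nan,
                se_candidate=np.nan,
                rank_p=np.nan,
                feasible=False,
                n_snps=0,
                error=str(exc),
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df["_fits"] = (df["rank_p"] >= rank_p_threshold).fillna(False)
    df = df.sort_values(
        by=["feasible", "_fits", "se_candidate"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df.drop(columns="_fits")
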