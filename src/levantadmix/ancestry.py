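"""Supervised ancestry decomposition and PCA with projection.

**Supervised ancestry EM.** Each individual's allele dosage at SNP m is
modeled Binomial(2, u_m) with u_m = sum_k q_k * p_km, where the reference
panel frequencies p_km are fixed and the ancestry fractions q live on the
simplex.  EM assigns each observed allele copy to a reference in
proportion to q_k * p_km / u_m (or the complementary term for the other
allele) and renormalizes; the log-likelihood is non-decreasing every
iteration and the problem is concave in q, so the symmetric start
q = 1/K needs no restarts.  Missing genotypes are skipped.

**PCA.** Fitted on modern (low-missingness) individuals: dosages centered
per SNP and scaled by sqrt(p(1-p)); residual missing entries are zeroed
after centering.  Ancient, high-missingness samples are *projected* by
least squares against the loadings restricted to each sample's observed
SNPs, which avoids the shrinkage toward the origin that zero-filling
would cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from levantadmix.data import AlleleFrequencySet, Dataset

_EPS = 1e-5


@dataclass
class AncestryProportions:
    """Per-individual ancestry fractions against K fixed references."""

    q: np.ndarray  # (n_ind, K), rows on the simplex
    ref_labels: list[str]
    ind_ids: list[str]
    loglik: np.ndarray  # per individual at convergence
    n_iter: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=self.ref_labels)
        df.insert(0, "ind_id", self.ind_ids)
        return df


def supervised_ancestry_em(
    geno: np.ndarray | Dataset,
    ref_afs: dict[str, AlleleFrequencySet],
    tol: float = 1e-6,
    max_iter: int = 2000,
    ind_ids: list[str] | None = None,
) -> AncestryProportions:
    """Ancestry fractions of each individual against fixed reference panels.

    ``geno`` is an (n_ind, n_snps) dosage matrix (or a Dataset) aligned
    with the reference frequency sets; reference frequencies are clipped
    to [1e-5, 1 - 1e-5].  Convergence: |delta loglik| < ``tol`` per
    individual (default 1e-6), capped at ``max_iter``.
    """
    if isinstance(geno, Dataset):
        ind_ids = list(geno.inds["ind_id"])
        geno = geno.geno
    geno = np.asarray(geno)
    if geno.ndim == 1:
        geno = geno[None, :]
    n_ind, n_snp = geno.shape
    labels = list(ref_afs)
    K = len(labels)
    if K < 1:
        raise ValueError("need at least one reference population")
    P = np.clip(np.stack([ref_afs[k].freq for k in labels]), _EPS, 1 - _EPS)  # (K, n_snp)
    if P.shape[1] != n_snp:
        raise ValueError("reference panels do not match the genotype SNP panel")
    if np.isnan(P).any():
        raise ValueError("reference frequencies contain NaN; fill or drop those SNPs first")

    q_out = np.empty((n_ind, K))
    ll_out = np.empty(n_ind)
    it_out = np.empty(n_ind, dtype=int)
    for i in range(n_ind):
        g = geno[i].astype(float)
        obs = g >= 0
        if not obs.any():
            raise ValueError(f"individual {i} has zero non-missing SNPs")
        gm = g[obs]
        Pm = P[:, obs]  # (K, M)
        Qm = 1.0 - Pm
        M = gm.size
        q = np.full(K, 1.0 / K)
        ll_prev = -np.inf
        it = 0
        for it in range(1, max_iter + 1):
            u = q @ Pm  # (M,)
            v = 1.0 - u
            ll = float(np.sum(gm * np.log(u) + (2.0 - gm) * np.log(v)))
            # E-step: expected allele-copy assignments per reference
            a_share = (q[:, None] * Pm) / u[None, :]
            b_share = (q[:, None] * Qm) / v[None, :]
            counts = a_share @ gm + b_share @ (2.0 - gm)
            q = counts / (2.0 * M)
            q = q / q.sum()
            if abs(ll - ll_prev) < tol:
                ll_prev = ll
                break
            ll_prev = ll
        q_out[i] = q
        ll_out[i] = ll_prev
        it_out[i] = it
    return AncestryProportions(
        q=q_out,
        ref_labels=labels,
        ind_ids=ind_ids if ind_ids is not None else [f"ind{i}" for i in range(n_ind)],
        loglik=ll_out,
        n_iter=it_out,
    )


@dataclass
class PCAModel:
    """PCA of normalized genotype dosages with stored training scores."""

    snp_ids: np.ndarray
    means: np.ndarray
    norms: np.ndarray  # sqrt(p(1-p)) per SNP
    loadings: np.ndarray = field(repr=False)  # (n_snps, k), orthonormal columns
    eigenvalues: np.ndarray
    scores: np.ndarray = field(repr=False)  # (n_train, k)
    ind_ids: list[str] = field(default_factory=list)


def pca_fit(ds: Dataset, k: int, max_missing: float = 0.5) -> PCAModel:
    """Fit PCA on modern individuals with < ``max_missing`` missingness.

    Dosages are centered by SNP mean and scaled by sqrt(p(1-p)) with
    p = mean/2; monomorphic SNPs are dropped; missing entries become 0
    after centering.  Raises if ``k`` exceeds the matrix rank.
    """
    miss_frac = (ds.geno < 0).mean(axis=1)
    keep_ind = miss_frac < max_missing
    if keep_ind.sum() < 2:
        raise ValueError("fewer than 2 individuals below the missingness ceiling")
    geno = ds.geno[keep_ind].astype(float)
    ind_ids = list(ds.inds.loc[keep_ind, "ind_id"])

    obs = geno >= 0
    n_calls = obs.sum(axis=0)
    means = np.where(n_calls > 0, np.where(obs, geno, 0.0).sum(axis=0) / np.maximum(n_calls, 1), np.nan)
    p = means / 2.0
    poly = (n_calls > 0) & (p > 0) & (p < 1)
    if poly.sum() == 0:
        raise ValueError("no polymorphic SNPs")
    geno = geno[:, poly]
    obs = obs[:, poly]
    means_p = means[poly]
    norms = np.sqrt(p[poly] * (1.0 - p[poly]))

    X = np.where(obs, (geno - means_p) / norms, 0.0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise ValueError(f"k = {k} exceeds matrix rank {rank}")
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    eigenvalues = (s[:k] ** 2) / max(X.shape[0] - 1, 1)
    return PCAModel(
        snp_ids=ds.snps.loc[poly, "snp_id"].to_numpy(),
        means=means_p,
        norms=norms,
        loadings=loadings,
        eigenvalues=eigenvalues,
        scores=scores,
        ind_ids=ind_ids,
    )


def pca_project(model: PCAModel, ds: Dataset, min_overlap: int = 1000) -> pd.DataFrame:
    """Project (possibly pseudo-haploid, high-missingness) samples.

    For each sample, solves the least-squares problem restricted to its
    observed SNPs shared with the model:

        min_s || x_obs - L_obs s ||^2

    so missing data does not pull scores toward the origin.  Requires at
    least ``min_overlap`` shared observed SNPs per sample.
    """
    id_to_col = {sid: j for j, sid in enumerate(model.snp_ids)}
    cols = np.array([id_to_col.get(sid, -1) for sid in ds.snps["snp_id"]])
    in_model = cols >= 0
    k = model.loadings.shape[1]
    rows = []
    for i in range(ds.n_inds):
        g = ds.geno[i].astype(float)
        obs = (g >= 0) & in_model
        mcols = cols[obs]
        n_obs = mcols.size
        if n_obs < min_overlap:
            raise ValueError(
                f"sample {ds.inds['ind_id'].iat[i]!r} shares only {n_obs} observed SNPs "
                f"with the model (floor {min_overlap})"
            )
        x = (g[obs] - model.means[mcols]) / model.norms[mcols]
        L = model.loadings[mcols]
        s, *_ = np.linalg.lstsq(L, x, rcond=None)
        rows.append(s)
    out = pd.DataFrame(np.vstack(rows), columns=[f"PC{j + 1}" for j in range(k)])
    out.insert(0, "ind_id", list(ds.inds["ind_id"]))
    return out
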