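"""Parameter-recovery benchmarks run on the synthetic generator.

Each function simulates data with known truth, runs the corresponding
inference path, and returns summary numbers.  They are deterministic
given their seed (replicate sub-seeds are spawned from it) and are used
both by the acceptance test suite and by ``scripts/acceptance.py``.

Problem sizes are desk scale: tens of thousands of SNPs and tens to
hundreds of individuals, enough for every recovery target while keeping
a full run in minutes.
"""

from __future__ import annotations

import numpy as np

from levantadmix.admixld import fit_decay, weighted_ld_curve
from levantadmix.ancestry import supervised_ancestry_em
from levantadmix.data import AlleleFrequencySet
from levantadmix.fstats import (
    f2_from_freqs,
    f3_from_freqs,
    f4,
    f4_from_freqs,
    make_blocks,
)
from levantadmix.genolike import GenotypeLikelihoods, estimate_af_em, genotype_priors
from levantadmix.mixmodel import MixtureModel, build_f4_system, fit_proportions
from levantadmix.simgraph import (
    DemographyGraph,
    MosaicSpec,
    sample_genotypes,
    simulate_admixed_haplotypes,
    simulate_graph_frequencies,
    two_source_benchmark,
)


def _sub(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))


def _uniform_blocks(n: int, n_blocks: int):
    from levantadmix.fstats import BlockPartition

    return BlockPartition(index=(np.arange(n) * n_blocks) // n, n_blocks=n_blocks)


def f4_oracle_agreement(seed: int, n_tables: int = 100) -> float:
    """Max |f-statistic - direct summation| over random frequency tables."""
    rng = np.random.default_rng(_sub(seed, 1))
    worst = 0.0
    for _ in range(n_tables):
        n = int(rng.integers(10, 60))
        pA, pB, pC, pD = (rng.uniform(0, 1, n) for _ in range(4))
        blocks = _uniform_blocks(n, max(2, n // 7))
        worst = max(
            worst,
            abs(f4_from_freqs(pA, pB, pC, pD, blocks).estimate - np.mean((pA - pB) * (pC - pD))),
            abs(f3_from_freqs(pA, pB, pC, blocks).estimate - np.mean((pA - pB) * (pA - pC))),
            abs(f2_from_freqs(pA, pB, blocks).estimate - np.mean((pA - pB) ** 2)),
        )
    return float(worst)


def jackknife_calibration(
    seed: int, n_rep: int = 100, n_snps: int = 3000, n_ind: int = 10
) -> float:
    """Mean jackknife SE over the empirical SD of f4 on homogeneous data."""
    graph = DemographyGraph(
        nodes=["R", "A", "B", "C", "D"], edges={k: ("R", 0.02) for k in "ABCD"}
    )
    ests, ses = [], []
    for rep in range(n_rep):
        freqs = simulate_graph_frequencies(graph, n_snps=n_snps, seed=_sub(seed, 2, rep, 0))
        ds = sample_genotypes(
            {k: freqs[k] for k in "ABCD"}, n_ind=n_ind, seed=_sub(seed, 2, rep, 1)
        )
        r = f4(ds, "A", "B", "C", "D", make_blocks(ds.snps))
        ests.append(r.estimate)
        ses.append(r.se)
    return float(np.mean(ses) / np.std(ests, ddof=1))


def mixture_recovery(
    seed: int,
    alphas: tuple = (0.2, 0.5, 0.8),
    taus: tuple = (0.005, 0.02, 0.05),
    n_rep: int = 20,
    n_snps: int = 20_000,
    n_ind: int = 10,
) -> dict:
    """Two-source proportion recovery over the (alpha, tau) grid.

    Returns the pooled fraction of replicates with |alpha_hat - alpha|
    <= 2 SE, the mean absolute error, and the rank-test rejection rate of
    a one-source model in the strongly admixed cell (alpha = 0.5, largest
    tau).
    """
    within = []
    abs_err = []
    rank_rejects = []
    for ai, alpha in enumerate(alphas):
        for ti, tau in enumerate(taus):
            graph, roles = two_source_benchmark(tau=tau, alpha=alpha)
            pops = [roles["target"], *roles["sources"], *roles["rights"]]
            for rep in range(n_rep):
                freqs = simulate_graph_frequencies(
                    graph, n_snps=n_snps, seed=_sub(seed, 3, ai, ti, rep, 0)
                )
                ds = sample_genotypes(
                    {p: freqs[p] for p in pops}, n_ind=n_ind,
                    seed=_sub(seed, 3, ai, ti, rep, 1),
                )
                blocks = make_blocks(ds.snps)
                model = MixtureModel(roles["target"], roles["sources"], roles["rights"])
                fit = fit_proportions(build_f4_system(ds, model, blocks))
                within.append(abs(fit.weights[0] - alpha) <= 2 * fit.se[0])
                abs_err.append(abs(fit.weights[0] - alpha))
                if alpha == 0.5 and tau == max(taus):
                    m1 = MixtureModel(
                        roles["target"], [roles["sources"][0]], roles["rights"]
                    )
                    p1 = fit_proportions(build_f4_system(ds, m1, blocks)).rank_p
                    rank_rejects.append(p1 < 0.01)
    return {
        "within_2se_rate": float(np.mean(within)),
        "mean_abs_error": float(np.mean(abs_err)),
        "rank_reject_rate": float(np.mean(rank_rejects)),
        "n_cells": len(alphas) * len(taus),
        "n_rep": n_rep,
    }


def date_recovery(
    seed: int,
    n_gens: tuple = (25, 50, 100, 200),
    n_rep: int = 10,
    n_controls: int = 10,
    n_ind: int = 200,
) -> dict:
    """Admixture-date recovery across pulse ages, plus unadmixed controls.

    Mosaic panels use the generator defaults (20 chromosomes x 1.5
    Morgans, 300 SNPs each, alpha = 0.5).  Returns the pooled fraction of
    replicates with |n_hat - n_gen| <= 2 se_n, the per-age median
    estimates, whether those medians increase strictly, and the controls'
    z-score behavior.
    """
    within = []
    medians = []
    for gi, n_gen in enumerate(n_gens):
        ests = []
        for rep in range(n_rep):
            spec = MosaicSpec(n_gen=float(n_gen), alpha=0.5)
            ds = simulate_admixed_haplotypes(spec, n_ind=n_ind, seed=_sub(seed, 4, gi, rep))
            p_a, p_b = ds.panel_freqs
            fit = fit_decay(weighted_ld_curve(ds, p_a - p_b))
            ests.append(fit.n_generations)
            within.append(abs(fit.n_generations - n_gen) <= 2 * fit.se_n)
        medians.append(float(np.median(ests)))
    control_z = []
    for rep in range(n_controls):
        spec = MosaicSpec(n_gen=0.0, alpha=1.0)
        ds = simulate_admixed_haplotypes(spec, n_ind=n_ind, seed=_sub(seed, 5, rep))
        p_a, p_b = ds.panel_freqs
        fit = fit_decay(weighted_ld_curve(ds, p_a - p_b))
        control_z.append(fit.z)
    return {
        "within_2se_rate": float(np.mean(within)),
        "medians": medians,
        "monotone": bool(all(a < b for a, b in zip(medians, medians[1:]))),
        "control_max_z": float(np.max(control_z)),
        "control_below_z2_rate": float(np.mean(np.asarray(control_z) < 2.0)),
    }


def ancestry_recovery(
    seed: int,
    q1_values: tuple = (0.1, 0.25, 0.5),
    n_rep: int = 20,
    n_snps: int = 50_000,
    tau: float = 0.05,
) -> float:
    """Mean |q1_hat - q1| for two-reference supervised decomposition.

    References drift tau from a shared root (Balding-Nichols); each
    replicate draws one individual from the q1 mixture of the reference
    frequencies.
    """
    graph = DemographyGraph(nodes=["R", "A", "B"], edges={"A": ("R", tau), "B": ("R", tau)})
    errs = []
    for qi, q1 in enumerate(q1_values):
        for rep in range(n_rep):
            freqs = simulate_graph_frequencies(graph, n_snps=n_snps, seed=_sub(seed, 6, qi, rep, 0))
            refs = {"A": freqs["A"], "B": freqs["B"]}
            rng = np.random.default_rng(_sub(seed, 6, qi, rep, 1))
            u = q1 * freqs["A"].freq + (1 - q1) * freqs["B"].freq
            g = rng.binomial(2, u, size=(1, n_snps))
            props = supervised_ancestry_em(g, refs)
            errs.append(abs(props.q[0, 0] - q1))
    return float(np.mean(errs))


def af_em_agreement(seed: int, n_tables: int = 100, grid_points: int = 10_001) -> float:
    """Max |EM frequency - grid-search ML| over random likelihood tables."""
    rng = np.random.default_rng(_sub(seed, 7))
    v = rng.uniform(0, 1, size=(3, n_tables, 3))
    v[rng.random(v.shape[:2]) < 0.3, 0] = 1.0
    gl = GenotypeLikelihoods(v)
    afs = estimate_af_em(gl)
    grid = np.linspace(0, 1, grid_points)
    priors = genotype_priors(grid)  # (grid, 3)
    mix = np.einsum("isg,pg->isp", gl.values, priors)
    ll = np.log(np.maximum(mix, 1e-300)).sum(axis=0)
    best = grid[np.argmax(ll, axis=1)]
    return float(np.nanmax(np.abs(afs.freq - best)))


def pipeline_determinism(seed: int, workdir: str) -> bool:
    """Run the simulation-preset pipeline twice; compare reports bytewise."""
    import os

    from levantadmix.pipeline import PipelineConfig, run_pipeline

    digests = []
    for tag in ("a", "b"):
        out = os.path.join(workdir, tag)
        cfg = PipelineConfig.from_dict(
            {
                "preset": "levant-sim",
                "seed": seed,
                "out_dir": out,
                "n_snps": 10_000,
                "analyses": [
                    {"stage": "mixture", "params": {}},
                    {"stage": "ancestry",
                     "params": {"refs": ["Levant_N", "Iran_ChL", "EHG", "WHG"]}},
                ],
            }
        )
        run_pipeline(cfg)
        with open(os.path.join(out, "report.json"), "rb") as fh:
            digests.append(fh.read())
    return digests[0] == digests[1]
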