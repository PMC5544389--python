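"""Configuration-driven orchestration of the full analysis recipe.

A pipeline run loads (or simulates) a genotype panel, then executes the
requested stages in order: f4 scans, mixture-proportion fits, admixture-LD
dating, supervised ancestry decomposition and PCA projection.  One master
seed deterministically derives every stage's randomness, so a repeated run
with the same config is byte-identical.

The ``levant-sim`` preset encodes a two-pulse demographic benchmark with
known truth: an ancient coastal population formed as a 50/50 mixture of a
Levantine-farmer-like and an Iranian-Chalcolithic-like source, and a
present-day population formed as a 93/7 mixture of that ancient population
with a steppe-related source, surrounded by hunter-gatherer and deep
outgroup panels.  Recovering the known proportions through the mixture
stage exercises the whole chain end to end.
"""

from __future__ import annotations

import json
import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import yaml

import levantadmix
from levantadmix.admixld import date_admixture, fit_decay, weighted_ld_curve
from levantadmix.ancestry import pca_fit, pca_project, supervised_ancestry_em
from levantadmix.data import Dataset
from levantadmix.eigenstrat import read_eigenstrat
from levantadmix.fstats import f4_scan, make_blocks, pop_frequencies
from levantadmix.mixmodel import MixtureModel, build_f4_system, fit_proportions
from levantadmix.simgraph import (
    DemographyGraph,
    MosaicSpec,
    sample_genotypes,
    simulate_admixed_haplotypes,
    simulate_graph_frequencies,
)
from levantadmix.vcfio import read_vcf_biallelic

logger = logging.getLogger("levantadmix")

REPORT_SCHEMA_VERSION = 1

KNOWN_STAGES = ("fstat-scan", "mixture", "date", "ancestry", "pca")

#: mixture proportions of the simulation preset (truth)
PRESET_ALPHA_ANCIENT = 0.5
PRESET_ALPHA_MODERN = 0.93


def preset_graph(
    alpha_ancient: float = PRESET_ALPHA_ANCIENT, alpha_modern: float = PRESET_ALPHA_MODERN
) -> DemographyGraph:
    """Two-pulse benchmark demography with hunter-gatherer outgroups."""
    nodes = [
        "Root", "Mbuti", "Eurasia", "Ust_Ishim", "Han", "WestEurasia",
        "WHG", "EHG", "Steppe_EMBA", "NearEast", "LevantAnc", "Levant_N",
        "Natufian", "IranAnc", "Iran_ChL", "CHG", "Sidon_BA_anc", "Sidon_BA",
        "Lebanese_anc", "Lebanese",
    ]
    edges = {
        "Mbuti": ("Root", 0.08),
        "Eurasia": ("Root", 0.02),
        "Ust_Ishim": ("Eurasia", 0.05),
        "Han": ("Eurasia", 0.06),
        "WestEurasia": ("Eurasia", 0.015),
        "WHG": ("WestEurasia", 0.05),
        "EHG": ("WestEurasia", 0.045),
        "Steppe_EMBA": ("EHG", 0.02),
        "NearEast": ("WestEurasia", 0.01),
        "LevantAnc": ("NearEast", 0.01),
        "Levant_N": ("LevantAnc", 0.01),
        "Natufian": ("LevantAnc", 0.02),
        "IranAnc": ("NearEast", 0.01),
        "Iran_ChL": ("IranAnc", 0.01),
        "CHG": ("IranAnc", 0.02),
        "Sidon_BA": ("Sidon_BA_anc", 0.005),
        "Lebanese": ("Lebanese_anc", 0.005),
    }
    admixtures = {
        "Sidon_BA_anc": ("Levant_N", "Iran_ChL", alpha_ancient),
        "Lebanese_anc": ("Sidon_BA", "Steppe_EMBA", alpha_modern),
    }
    return DemographyGraph(nodes=nodes, edges=edges, admixtures=admixtures)


PRESET_RIGHTS = ["Mbuti", "Ust_Ishim", "Han", "WHG", "EHG", "Natufian", "CHG"]
PRESET_SAMPLED = [
    "Mbuti", "Ust_Ishim", "Han", "WHG", "EHG", "Steppe_EMBA", "Levant_N",
    "Natufian", "Iran_ChL", "CHG", "Sidon_BA", "Lebanese",
]


def simulate_preset(
    seed: int, n_snps: int = 50_000, n_per_pop: int = 10
) -> tuple[Dataset, dict]:
    """Simulate the benchmark panel; returns the dataset and its truth."""
    ss = np.random.SeedSequence(seed)
    s_freq, s_geno = ss.spawn(2)
    graph = preset_graph()
    freqs = simulate_graph_frequencies(graph, n_snps=n_snps, seed=s_freq)
    ds = sample_genotypes({p: freqs[p] for p in PRESET_SAMPLED}, n_ind=n_per_pop, seed=s_geno)
    truth = {
        "Sidon_BA": {"Levant_N": PRESET_ALPHA_ANCIENT, "Iran_ChL": 1 - PRESET_ALPHA_ANCIENT},
        "Lebanese": {"Sidon_BA": PRESET_ALPHA_MODERN, "Steppe_EMBA": 1 - PRESET_ALPHA_MODERN},
    }
    return ds, truth


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int
    out_dir: str
    analyses: list[dict] = field(default_factory=list)
    preset: str | None = None
    eigenstrat: str | None = None
    vcf: str | None = None
    pop_map: str | None = None
    n_snps: int = 50_000
    n_per_pop: int = 10
    block_cm: float = 5.0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ValueError("config must set a master seed")
        cfg = cls(
            seed=int(raw["seed"]),
            out_dir=str(raw.get("out_dir", "levantadmix_out")),
            analyses=list(raw.get("analyses", [])),
            preset=raw.get("preset"),
            eigenstrat=raw.get("eigenstrat"),
            vcf=raw.get("vcf"),
            pop_map=raw.get("pop_map"),
            n_snps=int(raw.get("n_snps", 50_000)),
            n_per_pop=int(raw.get("n_per_pop", 10)),
            block_cm=float(raw.get("block_cm", 5.0)),
        )
        if not (cfg.preset or cfg.eigenstrat or cfg.vcf):
            raise ValueError("config needs a preset, an eigenstrat prefix or a vcf path")
        if cfg.preset is not None and cfg.preset not in ("levant-sim", "fig4a-sim"):
            raise ValueError(f"unknown preset {cfg.preset!r}")
        for entry in cfg.analyses:
            stage = entry.get("stage")
            if stage not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {stage!r}; known: {KNOWN_STAGES}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage_seed(master: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=(index,))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Writes ``report.json`` plus per-stage TSVs to the output directory;
    returns the report dict.  Raises on the first stage error after
    config-time validation.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "pipeline.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": levantadmix.__version__,
        "seed": config.seed,
        "stages": {},
    }
    try:
        truth: dict = {}
        if config.preset:
            ds, truth = simulate_preset_seeded(config)
            report["input"] = {"preset": config.preset, "truth": truth}
        elif config.eigenstrat:
            ds = read_eigenstrat(config.eigenstrat)
            report["input"] = {"eigenstrat": config.eigenstrat}
        else:
            ds = read_vcf_biallelic(config.vcf, config.pop_map)
            report["input"] = {"vcf": config.vcf}
        report["input"]["n_snps"] = ds.n_snps
        report["input"]["n_inds"] = ds.n_inds
        logger.info("loaded panel: %d SNPs, %d individuals", ds.n_snps, ds.n_inds)

        missing = set()
        for entry in config.analyses:
            for key in ("pops", "sources", "rights", "refs", "candidates"):
                for p in entry.get("params", {}).get(key, []) or []:
                    if p not in ds.populations:
                        missing.add(p)
        if missing:
            raise ValueError(f"populations not in panel: {sorted(missing)}")

        blocks = make_blocks(ds.snps, block_cm=config.block_cm)
        for idx, entry in enumerate(config.analyses, start=1):
            stage = entry["stage"]
            params = entry.get("params", {})
            seed = _stage_seed(config.seed, idx)
            logger.info("stage %s", stage)
            report["stages"][f"{idx}:{stage}"] = _run_stage(
                stage, params, ds, blocks, truth, seed, config
            )
    finally:
        logger.removeHandler(handler)
        handler.close()

    out_path = os.path.join(config.out_dir, "report.json")
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def simulate_preset_seeded(config: PipelineConfig) -> tuple[Dataset, dict]:
    ss = _stage_seed(config.seed, 0)
    graph = preset_graph()
    s_freq, s_geno = ss.spawn(2)
    freqs = simulate_graph_frequencies(graph, n_snps=config.n_snps, seed=s_freq)
    ds = sample_genotypes(
        {p: freqs[p] for p in PRESET_SAMPLED}, n_ind=config.n_per_pop, seed=s_geno
    )
    truth = {
        "Sidon_BA": {"Levant_N": PRESET_ALPHA_ANCIENT, "Iran_ChL": 1 - PRESET_ALPHA_ANCIENT},
        "Lebanese": {"Sidon_BA": PRESET_ALPHA_MODERN, "Steppe_EMBA": 1 - PRESET_ALPHA_MODERN},
    }
    return ds, truth


def _run_stage(stage, params, ds, blocks, truth, seed, config) -> dict:
    if stage == "fstat-scan":
        fixed = params.get("fixed_triple", ["Lebanese", "Sidon_BA", "Mbuti"])
        cands = params.get("candidates") or [
            p for p in ds.populations if p not in fixed
        ]
        table = f4_scan(ds, tuple(fixed), cands, blocks, slot=int(params.get("slot", 1)))
        path = os.path.join(config.out_dir, "fstat_scan.tsv")
        table.to_csv(path, sep="\t", index=False)
        top = table.iloc[0]
        return {
            "table": os.path.basename(path),
            "n_candidates": len(table),
            "most_negative_z": {"candidate": str(top["candidate"]), "z": float(top["z"])},
        }
    if stage == "mixture":
        target = params.get("target", "Sidon_BA")
        sources = params.get("sources", ["Levant_N", "Iran_ChL"])
        rights = params.get("rights", PRESET_RIGHTS)
        model = MixtureModel(target, list(sources), list(rights), allsnps=params.get("allsnps", True))
        fit = fit_proportions(build_f4_system(ds, model, blocks))
        out = fit.to_dict()
        if target in truth:
            out["truth"] = truth[target]
        return out
    if stage == "date":
        spec = MosaicSpec(
            n_gen=float(params.get("n_gen", 100.0)),
            alpha=float(params.get("alpha", 0.5)),
            map_length=float(params.get("map_length", 1.5)),
            n_chrom=int(params.get("n_chrom", 20)),
            snps_per_chrom=int(params.get("snps_per_chrom", 300)),
        )
        s_mosaic, s_refs = seed.spawn(2)
        mosaic = simulate_admixed_haplotypes(spec, n_ind=int(params.get("n_ind", 200)), seed=s_mosaic)
        p_a, p_b = mosaic.panel_freqs
        delta = p_a - p_b
        curve = weighted_ld_curve(
            mosaic, delta,
            min_d=float(params.get("mindis", 0.005)),
            max_d=float(params.get("maxdis", 0.3)),
            bin_width=float(params.get("bin_width", 0.0005)),
        )
        fit = fit_decay(curve)
        gen_time = float(params.get("gen_time", 28.0))
        date = date_admixture(fit, generation_time=gen_time, force=True)
        return {
            "truth_n_gen": spec.n_gen,
            "n_generations": fit.n_generations,
            "se_n": fit.se_n,
            "z": fit.z,
            "amplitude": fit.amplitude,
            "affine": fit.affine,
            "years": date.years,
            "se_years": date.se_years,
            "generation_time": gen_time,
        }
    if stage == "ancestry":
        refs = params.get("refs", ["Levant_N", "Iran_ChL", "EHG", "WHG"])
        targets = params.get("targets", ["Sidon_BA", "Lebanese"])
        ref_afs = pop_frequencies(ds, refs)
        # drop SNPs any reference lacks
        ok = np.ones(ds.n_snps, dtype=bool)
        for r in refs:
            ok &= ~np.isnan(ref_afs[r].freq)
        sub = ds.subset_snps(ok)
        ref_afs = pop_frequencies(sub, refs)
        rows = np.concatenate([sub.ind_indices(t) for t in targets])
        props = supervised_ancestry_em(
            sub.geno[rows], ref_afs, ind_ids=list(sub.inds["ind_id"].iloc[rows])
        )
        path = os.path.join(config.out_dir, "ancestry_q.tsv")
        props.to_frame().to_csv(path, sep="\t", index=False)
        mean_q = {
            t: {r: float(np.mean(props.q[[i for i, iid in enumerate(props.ind_ids)
                                          if iid.startswith(t)], k])) for k, r in enumerate(refs)}
            for t in targets
        }
        return {"table": os.path.basename(path), "mean_q": mean_q}
    if stage == "pca":
        modern = params.get("modern_pops") or [p for p in ds.populations if p != params.get("project", "Sidon_BA")]
        project = params.get("project", "Sidon_BA")
        keep = ds.inds["population"].isin(modern).to_numpy()
        modern_ds = Dataset(ds.snps.copy(), ds.inds.loc[keep], ds.geno[keep])
        model = pca_fit(modern_ds, k=int(params.get("k", 4)))
        anc_keep = (ds.inds["population"] == project).to_numpy()
        anc_ds = Dataset(ds.snps.copy(), ds.inds.loc[anc_keep], ds.geno[anc_keep])
        scores = pca_project(model, anc_ds, min_overlap=int(params.get("min_overlap", 1000)))
        path = os.path.join(config.out_dir, "pca_projected.tsv")
        scores.to_csv(path, sep="\t", index=False)
        return {
            "table": os.path.basename(path),
            "k": int(params.get("k", 4)),
            "eigenvalues": [float(e) for e in model.eigenvalues],
        }
    raise ValueError(f"unknown stage {stage!r}")
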