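"""Synthetic admixture-graph panels and admixed haplotype mosaics.

Two generative models with fully known truth:

* **Admixture graph** (:class:`DemographyGraph`): per-SNP allele
  frequencies start at the root (uniform on [0.05, 0.95] by default) and
  evolve down drift edges under the Balding-Nichols model — the child
  frequency is Beta(p(1-tau)/tau, (1-p)(1-tau)/tau), so tau is the
  expected scaled variance E[(p_child - p)^2] = tau * p(1-p), directly on
  the f2 scale.  Admixed nodes mix their two parents' frequencies,
  p = alpha * p_A + (1 - alpha) * p_B.

* **Haplotype mosaic** (:class:`MosaicSpec`): an admixed population n_gen
  generations after a two-source pulse.  Ancestry switch points along each
  chromosome follow a Poisson process of rate n_gen per Morgan; each tract
  draws ancestry A with probability alpha; alleles are Bernoulli draws
  from the tract ancestry's panel frequency.  This produces the
  exponentially decaying admixture LD, with decay constant n_gen, that the
  dating module estimates.

Genotype sampling is Binomial(2, p); aDNA-style corruption pseudo-
haploidizes, masks genotypes at a missingness rate and flips surviving
haploid calls at an error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from levantadmix.data import (
    MISSING,
    AlleleFrequencySet,
    Dataset,
    make_ind_table,
    make_snp_table,
    pseudo_haploidize,
)


@dataclass
class DemographyGraph:
    """Population relationships: drift edges and two-parent admixture events.

    ``edges`` maps child -> (parent, tau) with drift tau >= 0;
    ``admixtures`` maps child -> (parentA, parentB, alpha) with alpha the
    proportion inherited from parentA.  Every non-root node has exactly one
    of the two; the graph must be acyclic with a single root.
    """

    nodes: list[str]
    edges: dict[str, tuple[str, float]] = field(default_factory=dict)
    admixtures: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    root_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        parents = set(self.edges) | set(self.admixtures)
        overlap = set(self.edges) & set(self.admixtures)
        if overlap:
            raise ValueError(f"nodes with both drift and admixture parents: {sorted(overlap)}")
        roots = [n for n in self.nodes if n not in parents]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, found {roots}")
        for child, (_, tau) in self.edges.items():
            if tau < 0:
                raise ValueError(f"negative drift on edge to {child!r}")
        for child, (_, _, alpha) in self.admixtures.items():
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"admixture proportion for {child!r} outside [0, 1]")
        self.topological_order()  # raises on cycles / unknown parents

    @property
    def root(self) -> str:
        parents = set(self.edges) | set(self.admixtures)
        return next(n for n in self.nodes if n not in parents)

    def topological_order(self) -> list[str]:
        order: list[str] = []
        placed: set[str] = set()
        pending = list(self.nodes)
        while pending:
            progressed = False
            for n in list(pending):
                if n in self.edges:
                    deps = [self.edges[n][0]]
                elif n in self.admixtures:
                    deps = [self.admixtures[n][0], self.admixtures[n][1]]
                else:
                    deps = []
                unknown = [d for d in deps if d not in self.nodes]
                if unknown:
                    raise ValueError(f"unknown parent(s) {unknown} of node {n!r}")
                if all(d in placed for d in deps):
                    order.append(n)
                    placed.add(n)
                    pending.remove(n)
                    progressed = True
            if not progressed:
                raise ValueError(f"cycle in graph involving {pending}")
        return order


@dataclass
class MosaicSpec:
    """Truth parameters for an admixed haplotype mosaic.

    ``n_gen`` generations since a single two-source pulse; ``alpha``
    proportion of ancestry from panel A; ``n_chrom`` chromosomes each of
    ``map_length`` Morgans carrying ``snps_per_chrom`` markers; panel
    frequencies (p_A, p_B) drawn independently uniform on ``freq_range``
    per SNP (default [0.1, 0.9], keeping the weights delta = p_A - p_B
    informative), or supplied explicitly via ``panel_freqs``.
    """

    n_gen: float
    alpha: float
    map_length: float = 1.5
    n_chrom: int = 20
    snps_per_chrom: int = 300
    freq_range: tuple[float, float] = (0.1, 0.9)
    panel_freqs: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_gen < 0:
            raise ValueError("n_gen must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def simulate_graph_frequencies(
    graph: DemographyGraph, n_snps: int, seed: int
) -> dict[str, AlleleFrequencySet]:
    """Draw per-SNP allele frequencies for every node of the graph.

    Root frequencies are uniform on the graph's ``root_freq_range``; drift
    edges apply Balding-Nichols sampling (tau = 0 copies the parent);
    admixture nodes mix parent frequencies linearly.  Frequencies are
    clipped to [0, 1].  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = graph.root_freq_range
    freqs: dict[str, np.ndarray] = {}
    for node in graph.topological_order():
        if node in graph.edges:
            parent, tau = graph.edges[node]
            p = freqs[parent]
            if tau == 0:
                freqs[node] = p.copy()
            else:
                # Balding-Nichols: Beta with mean p, variance tau*p*(1-p)
                scale = (1.0 - tau) / tau
                a = np.maximum(p * scale, 1e-9)
                b = np.maximum((1.0 - p) * scale, 1e-9)
                drawn = rng.beta(a, b)
                # fixed parent frequencies stay fixed
                drawn = np.where(p <= 0, 0.0, np.where(p >= 1, 1.0, drawn))
                freqs[node] = np.clip(drawn, 0.0, 1.0)
        elif node in graph.admixtures:
            pa, pb, alpha = graph.admixtures[node]
            freqs[node] = np.clip(alpha * freqs[pa] + (1.0 - alpha) * freqs[pb], 0.0, 1.0)
        else:
            freqs[node] = rng.uniform(lo, hi, size=n_snps)
    return {node: AlleleFrequencySet(freq=f, n=np.full(n_snps, np.inf)) for node, f in freqs.items()}


def default_snp_table(n_snps: int, n_chrom: int = 20, chrom_cm: float = 150.0) -> pd.DataFrame:
    """Evenly spaced SNP map: ``n_snps`` markers over ``n_chrom`` chromosomes
    of ``chrom_cm`` centimorgans each, 1 cM per Mb."""
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps % n_chrom] += 1
    chroms, gpos, ppos = [], [], []
    for c in range(n_chrom):
        k = per[c]
        if k == 0:
            continue
        g = (np.arange(k) + 0.5) / k * (chrom_cm / 100.0)
        chroms.extend([str(c + 1)] * k)
        gpos.extend(g)
        ppos.extend(np.round(g * 1e8).astype(np.int64) + 1)
    return make_snp_table(
        chrom=np.asarray(chroms), physical_pos=np.asarray(ppos), genetic_pos=np.asarray(gpos)
    )


def sample_genotypes(
    freqs: dict[str, AlleleFrequencySet] | AlleleFrequencySet,
    n_ind: int | dict[str, int],
    seed: int,
    snps: pd.DataFrame | None = None,
) -> Dataset:
    """Sample diploid genotypes Binomial(2, p) for one or many populations.

    ``freqs`` maps population label to its frequency set (a bare set is
    treated as one population "pop0"); ``n_ind`` is a shared count or a
    per-population mapping.  A default evenly spaced SNP map is attached
    unless ``snps`` is given.
    """
    if isinstance(freqs, AlleleFrequencySet):
        freqs = {"pop0": freqs}
    rng = np.random.default_rng(seed)
    n_snps = len(next(iter(freqs.values())))
    rows = []
    ids, pops = [], []
    for label, afs in freqs.items():
        k = n_ind[label] if isinstance(n_ind, dict) else n_ind
        p = np.nan_to_num(afs.freq, nan=0.0)
        rows.append(rng.binomial(2, p, size=(k, n_snps)).astype(np.int8))
        ids.extend(f"{label}_{i}" for i in range(k))
        pops.extend([label] * k)
    snp_table = snps if snps is not None else default_snp_table(n_snps)
    return Dataset(snp_table, make_ind_table(ids, pops), np.concatenate(rows, axis=0))


def simulate_admixed_haplotypes(spec: MosaicSpec, n_ind: int, seed: int) -> Dataset:
    """Simulate diploid individuals as two independent ancestry mosaics.

    Per haplotype per chromosome, ancestry switch points are a Poisson
    process of rate ``spec.n_gen`` per Morgan; tract ancestries are i.i.d.
    Bernoulli(alpha) (A with probability alpha); each SNP allele is a
    Bernoulli draw from its tract's panel frequency.  The returned Dataset
    carries collapsed diploid genotypes, the phased ``haplotypes`` array
    and a per-haplotype ancestry-A fraction (``ancestry_fraction``).
    """
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_ind
    per_chrom = spec.snps_per_chrom
    n_snps = per_chrom * spec.n_chrom

    if spec.panel_freqs is not None:
        p_a, p_b = (np.asarray(f, dtype=float) for f in spec.panel_freqs)
        if p_a.shape != (n_snps,) or p_b.shape != (n_snps,):
            raise ValueError(f"panel_freqs must each have length {n_snps}")
    else:
        lo, hi = spec.freq_range
        p_a = rng.uniform(lo, hi, size=n_snps)
        p_b = rng.uniform(lo, hi, size=n_snps)

    chroms, gpos = [], []
    for c in range(spec.n_chrom):
        g = np.sort(rng.uniform(0.0, spec.map_length, size=per_chrom))
        chroms.extend([str(c + 1)] * per_chrom)
        gpos.append(g)

    ancestry = np.empty((n_hap, n_snps), dtype=np.int8)
    bp_counts = np.zeros(n_hap, dtype=np.int64)
    for c in range(spec.n_chrom):
        g = gpos[c]
        sl = slice(c * per_chrom, (c + 1) * per_chrom)
        for h in range(n_hap):
            n_bp = rng.poisson(spec.n_gen * spec.map_length)
            bp_counts[h] += n_bp
            if n_bp:
                bps = np.sort(rng.uniform(0.0, spec.map_length, size=n_bp))
            else:
                bps = np.empty(0)
            tract_anc = rng.random(n_bp + 1) < spec.alpha  # True = ancestry A
            ancestry[h, sl] = tract_anc[np.searchsorted(bps, g)]
    p_site = np.where(ancestry == 1, p_a[None, :], p_b[None, :])
    hap = (rng.random((n_hap, n_snps)) < p_site).astype(np.int8)

    geno = (hap[0::2] + hap[1::2]).astype(np.int8)

    # physical positions: 1 cM/Mb, jittered index to stay strictly increasing
    gcat = np.concatenate(gpos)
    ppos = np.round(gcat * 1e8).astype(np.int64) + np.concatenate(
        [np.arange(per_chrom)] * spec.n_chrom
    )
    snp_table = make_snp_table(chrom=np.asarray(chroms), physical_pos=ppos, genetic_pos=gcat)
    inds = make_ind_table([f"adm_{i}" for i in range(n_ind)], ["admixed"] * n_ind)
    ds = Dataset(snp_table, inds, geno, haplotypes=hap)
    ds.ancestry_fraction = ancestry.mean(axis=1)  # type: ignore[attr-defined]
    ds.panel_freqs = (p_a, p_b)  # type: ignore[attr-defined]
    ds.breakpoint_counts = bp_counts  # type: ignore[attr-defined]
    return ds


def two_source_benchmark(tau: float, alpha: float) -> tuple[DemographyGraph, dict]:
    """Parametric two-source admixture graph for recovery experiments.

    Two source populations S1, S2 sit on diverged lineages with terminal
    drift ``tau`` each; the target T is an ``alpha``/(1-alpha) mixture of
    them followed by a small private drift.  Rights: one deep outgroup
    (the base), one sister of each source's lineage and two further
    outgroup branches, giving the mixture system full column rank.

    Returns the graph and a role map with keys ``target``, ``sources``,
    ``rights`` and ``alpha``.
    """
    nodes = [
        "Root", "Rbase", "R3", "R4", "X1", "S1", "U1", "X2", "S2", "U2",
        "T_anc", "T",
    ]
    edges = {
        "Rbase": ("Root", 0.02),
        "R3": ("Root", 0.03),
        "R4": ("Root", 0.025),
        "X1": ("Root", 0.01),
        "S1": ("X1", tau),
        "U1": ("X1", 0.02),
        "X2": ("Root", 0.01),
        "S2": ("X2", tau),
        "U2": ("X2", 0.02),
        "T": ("T_anc", 0.005),
    }
    admixtures = {"T_anc": ("S1", "S2", alpha)}
    graph = DemographyGraph(nodes=nodes, edges=edges, admixtures=admixtures)
    roles = {
        "target": "T",
        "sources": ["S1", "S2"],
        "rights": ["Rbase", "U1", "U2", "R3", "R4"],
        "alpha": alpha,
    }
    return graph, roles


def corrupt_to_ancient(ds: Dataset, missing_rate: float, error_rate: float, seed: int) -> Dataset:
    """Degrade a diploid panel to aDNA-style pseudo-haploid data.

    Pseudo-haploidize, then mask each genotype MISSING with probability
    ``missing_rate``, then flip each surviving haploid call (0 <-> 2) with
    probability ``error_rate``.
    """
    if not (0.0 <= missing_rate <= 1.0 and 0.0 <= error_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    s_ph, s_rest = ss.spawn(2)
    out = pseudo_haploidize(ds, seed=s_ph)
    rng = np.random.default_rng(s_rest)
    geno = out.geno
    miss = rng.random(geno.shape) < missing_rate
    geno[miss] = MISSING
    flip = (rng.random(geno.shape) < error_rate) & (geno != MISSING)
    geno[flip] = 2 - geno[flip]
    return Dataset(out.snps, out.inds, geno)
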