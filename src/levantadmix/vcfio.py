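"""Biallelic-SNP import from VCF via cyvcf2.

Only biallelic SNP records are retained; indels, multiallelic and other
non-SNP records are dropped and counted.  ``allele_a`` is the REF allele,
so genotypes count REF copies (hom-ref = 2).  VCFs carry no genetic map;
genetic positions default to physical position x 1e-8 Morgans (1 cM/Mb)
and can be replaced afterwards from a proper map.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from levantadmix.data import MISSING, Dataset, make_ind_table, make_snp_table

_BASES = {"A", "C", "G", "T"}


def read_pop_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read a two-column whitespace-separated (ind_id, population) table."""
    return pd.read_csv(
        os.fspath(path), sep=r"\s+", header=None, names=["ind_id", "population"], dtype=str
    )


def read_vcf_biallelic(
    path: str | os.PathLike, pop_map: pd.DataFrame | str | os.PathLike
) -> Dataset:
    """Read biallelic SNPs with GT calls from a VCF into a :class:`Dataset`.

    ``pop_map`` maps ``ind_id`` to a population label (DataFrame or path to
    a two-column text file); samples absent from the map get label
    ``"unknown"``.  Drop counts are recorded on the result as ``vcf_log``.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, pd.DataFrame):
        pop_map = read_pop_map(pop_map)
    pops = dict(zip(pop_map["ind_id"], pop_map["population"]))

    vcf = VCF(os.fspath(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)

    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    ref_alleles: list[str] = []
    alt_alleles: list[str] = []
    geno_cols: list[np.ndarray] = []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_dropped += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 no call
        gt = np.asarray(v.gt_types)
        col = (2 - gt).astype(np.int8)  # count REF copies
        col[gt == 3] = MISSING
        geno_cols.append(col)
        chroms.append(v.CHROM)
        positions.append(v.POS)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        ref_alleles.append(v.REF)
        alt_alleles.append(v.ALT[0])

    if not geno_cols:
        raise ValueError(f"{path}: no biallelic SNP records with GT calls")

    snps = make_snp_table(
        chrom=np.asarray(chroms),
        physical_pos=np.asarray(positions, dtype=np.int64),
        genetic_pos=np.asarray(positions, dtype=float) * 1e-8,
        allele_a=ref_alleles,
        allele_b=alt_alleles,
        snp_id=ids,
    )
    inds = make_ind_table(samples, [pops.get(s, "unknown") for s in samples])
    ds = Dataset(snps, inds, np.column_stack(geno_cols))
    ds.vcf_log = {"n_retained": len(geno_cols), "n_dropped_non_biallelic_snp": n_dropped}  # type: ignore[attr-defined]
    return ds
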