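"""EIGENSTRAT geno/snp/ind reading and writing.

The .geno file holds one row per SNP, one character per individual in
{0, 1, 2, 9} (9 = missing), counting copies of the .snp table's fifth
column allele (``allele_a`` here).  The .snp columns are: id, chromosome,
genetic position (Morgans), physical position (bp, 1-based), allele_a,
allele_b.  The .ind columns are: id, sex (M/F/U), population label.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from levantadmix.data import MISSING, Dataset


class EigenstratParseError(ValueError):
    """Structured parse failure carrying the offending file and line."""

    def __init__(self, path: str, line: int, message: str):
        self.path = path
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def read_eigenstrat(prefix: str | os.PathLike) -> Dataset:
    """Read a ``prefix``.geno/.snp/.ind triplet into a :class:`Dataset`."""
    prefix = os.fspath(prefix)
    snp_path, ind_path, geno_path = f"{prefix}.snp", f"{prefix}.ind", f"{prefix}.geno"
    for p in (snp_path, ind_path, geno_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)

    snp_names = ["snp_id", "chrom", "genetic_pos", "physical_pos", "allele_a", "allele_b"]
    if os.path.getsize(snp_path) == 0:
        snps = pd.DataFrame(columns=snp_names).astype(
            {"genetic_pos": float, "physical_pos": np.int64}
        )
    else:
        snps = pd.read_csv(
            snp_path,
            sep=r"\s+",
            header=None,
            names=snp_names,
            dtype={"snp_id": str, "chrom": str, "allele_a": str, "allele_b": str},
        )
    inds = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=["ind_id", "sex", "population"], dtype=str
    )

    n_ind, n_snp = len(inds), len(snps)
    geno = np.empty((n_ind, n_snp), dtype=np.int8)
    with open(geno_path) as fh:
        row = -1
        for row, line in enumerate(fh):
            line = line.strip()
            if row >= n_snp:
                raise EigenstratParseError(geno_path, row + 1, f"more geno rows than {n_snp} SNPs")
            if len(line) != n_ind:
                raise EigenstratParseError(
                    geno_path, row + 1, f"expected {n_ind} genotype characters, got {len(line)}"
                )
            codes = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            if not np.isin(codes, (0, 1, 2, 9)).all():
                bad = chr(codes[~np.isin(codes, (0, 1, 2, 9))][0] + ord("0"))
                raise EigenstratParseError(geno_path, row + 1, f"invalid genotype character {bad!r}")
            geno[:, row] = codes
        if row + 1 != n_snp:
            raise EigenstratParseError(geno_path, row + 1, f"expected {n_snp} geno rows, got {row + 1}")
    geno[geno == 9] = MISSING
    return Dataset(snps, inds, geno)


def write_eigenstrat(ds: Dataset, prefix: str | os.PathLike) -> None:
    """Write ``ds`` as ``prefix``.geno/.snp/.ind (round-trips losslessly)."""
    prefix = os.fspath(prefix)
    with open(f"{prefix}.snp", "w") as fh:
        for row in ds.snps.itertuples(index=False):
            fh.write(
                f"{row.snp_id}\t{row.chrom}\t{row.genetic_pos:.10g}\t"
                f"{row.physical_pos}\t{row.allele_a}\t{row.allele_b}\n"
            )
    with open(f"{prefix}.ind", "w") as fh:
        for row in ds.inds.itertuples(index=False):
            fh.write(f"{row.ind_id}\t{row.sex}\t{row.population}\n")
    codes = ds.geno.astype(np.int16)
    codes[codes == MISSING] = 9
    chars = (codes + ord("0")).astype(np.uint8)
    with open(f"{prefix}.geno", "wb") as fh:
        for j in range(ds.n_snps):
            fh.write(chars[:, j].tobytes())
            fh.write(b"\n")
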