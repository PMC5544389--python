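"""I/O, merging and pseudo-haploidization of genotype panels."""

import numpy as np
import pandas as pd
import pytest

from levantadmix.data import (
    MISSING,
    Dataset,
    intersect_datasets,
    make_ind_table,
    make_snp_table,
    pseudo_haploidize,
)
from levantadmix.eigenstrat import EigenstratParseError, read_eigenstrat, write_eigenstrat
from levantadmix.vcfio import read_vcf_biallelic

from conftest import random_dataset


def two_by_two(tmp_path):
    """2-SNP, 2-individual EIGENSTRAT fixture with geno lines 09 / 21."""
    (tmp_path / "t.snp").write_text("s1 1 0.01 100 A G\ns2 1 0.02 200 C T\n")
    (tmp_path / "t.ind").write_text("i1 M popA\ni2 F popB\n")
    (tmp_path / "t.geno").write_text("09\n21\n")
    return tmp_path / "t"


class TestEigenstrat:
    def test_character_decoding(self, tmp_path):
        ds = read_eigenstrat(two_by_two(tmp_path))
        # geno rows are SNPs; the in-memory matrix is individuals x SNPs
        assert ds.geno.tolist() == [[0, 2], [MISSING, 1]]

    def test_nine_is_missing_everywhere(self, tmp_path):
        (tmp_path / "m.snp").write_text("s1 1 0.01 100 A G\n")
        (tmp_path / "m.ind").write_text("i1 U p\ni2 U p\ni3 U p\n")
        (tmp_path / "m.geno").write_text("999\n")
        ds = read_eigenstrat(tmp_path / "m")
        assert (ds.geno == MISSING).all()

    def test_dimension_mismatch_names_line(self, tmp_path):
        prefix = two_by_two(tmp_path)
        (tmp_path / "t.geno").write_text("09\n210\n")
        with pytest.raises(EigenstratParseError, match=r"geno:2"):
            read_eigenstrat(prefix)

    def test_roundtrip_random(self, tmp_path, rng):
        ds = random_dataset(rng, n_ind=20, n_snps=50)
        write_eigenstrat(ds, tmp_path / "rt")
        back = read_eigenstrat(tmp_path / "rt")
        assert np.array_equal(back.geno, ds.geno)
        pd.testing.assert_frame_equal(back.inds, ds.inds)
        pd.testing.assert_frame_equal(
            back.snps.drop(columns="genetic_pos"), ds.snps.drop(columns="genetic_pos")
        )
        assert np.allclose(back.snps["genetic_pos"], ds.snps["genetic_pos"], rtol=1e-9)

    def test_roundtrip_empty(self, tmp_path):
        ds = Dataset(
            make_snp_table(np.empty(0), np.empty(0, dtype=np.int64), np.empty(0)),
            make_ind_table(["i1"], ["p"]),
            np.empty((1, 0), dtype=np.int8),
        )
        write_eigenstrat(ds, tmp_path / "e")
        back = read_eigenstrat(tmp_path / "e")
        assert back.n_snps == 0 and back.n_inds == 1

    def test_missing_written_as_nine(self, tmp_path, rng):
        ds = random_dataset(rng, n_ind=5, n_snps=10, missing_rate=0.5)
        write_eigenstrat(ds, tmp_path / "n")
        text = (tmp_path / "n.geno").read_text()
        assert ("9" in text) == bool((ds.geno == MISSING).any())


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
"""


def write_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(records))
    return path


class TestVcf:
    def test_het_call_counts_ref(self, tmp_path):
        vcf = write_vcf(tmp_path / "a.vcf", ["1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"])
        pop_map = pd.DataFrame({"ind_id": ["s1", "s2"], "population": ["p", "p"]})
        ds = read_vcf_biallelic(vcf, pop_map)
        assert ds.geno.tolist() == [[1], [0]]
        assert list(ds.snps["allele_a"]) == ["A"]

    def test_non_biallelic_dropped(self, tmp_path):
        records = []
        # 15 clean SNPs
        for i in range(15):
            records.append(f"1\t{100 + i * 10}\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n")
        # 3 multiallelic + 2 indels
        records.append("1\t900\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/0\n")
        records.append("1\t910\t.\tC\tG,A\t.\t.\t.\tGT\t0/1\t0/0\n")
        records.append("1\t920\t.\tG\tC,T\t.\t.\t.\tGT\t0/1\t0/0\n")
        records.append("1\t930\t.\tAT\tA\t.\t.\t.\tGT\t0/1\t0/0\n")
        records.append("1\t940\t.\tC\tCAA\t.\t.\t.\tGT\t0/1\t0/0\n")
        vcf = write_vcf(tmp_path / "b.vcf", records)
        pop_map = pd.DataFrame({"ind_id": ["s1", "s2"], "population": ["p", "p"]})
        ds = read_vcf_biallelic(vcf, pop_map)
        assert ds.n_snps == 15
        assert ds.vcf_log["n_dropped_non_biallelic_snp"] == 5


def simple_ds(geno, alleles, ind_prefix="a"):
    n_ind, n_snp = np.asarray(geno).shape
    snps = make_snp_table(
        chrom=np.ones(n_snp, dtype=int),
        physical_pos=np.arange(1, n_snp + 1) * 100,
        genetic_pos=np.arange(n_snp) * 0.01,
        allele_a=[x[0] for x in alleles],
        allele_b=[x[1] for x in alleles],
    )
    inds = make_ind_table([f"{ind_prefix}{i}" for i in range(n_ind)], ["p_" + ind_prefix] * n_ind)
    return Dataset(snps, inds, np.asarray(geno, dtype=np.int8))


class TestIntersect:
    def test_identical_union(self, rng):
        ds = random_dataset(rng, n_ind=4, n_snps=10)
        other = Dataset(ds.snps.copy(), ds.inds.assign(ind_id=ds.inds.ind_id + "_b"), ds.geno.copy())
        merged = intersect_datasets(ds, other)
        assert merged.n_snps == ds.n_snps
        assert merged.n_inds == 2 * ds.n_inds

    def test_swapped_alleles_recode(self):
        a = simple_ds([[0, 2]], [("A", "G"), ("C", "T")], "a")
        b = simple_ds([[2, 1]], [("G", "A"), ("C", "T")], "b")  # first SNP swapped
        merged = intersect_datasets(a, b)
        # b's genotype at the swapped SNP recoded 2 -> 0
        assert merged.geno.tolist() == [[0, 2], [0, 1]]

    def test_shared_private_ambiguous_counts(self):
        # a: 3 reconcilable shared + 1 ambiguous shared + 2 private
        a = simple_ds([[0, 1, 2, 1, 0, 2]],
                      [("A", "G"), ("C", "T"), ("G", "T"), ("A", "T"), ("A", "C"), ("G", "T")], "a")
        b_snps = make_snp_table(
            chrom=np.ones(4, dtype=int),
            physical_pos=[100, 200, 300, 400],
            genetic_pos=[0.0, 0.01, 0.02, 0.03],
            allele_a=["A", "C", "G", "A"],
            allele_b=["G", "T", "T", "T"],
        )
        b = Dataset(b_snps, make_ind_table(["b0"], ["p_b"]), np.array([[0, 1, 2, 0]], dtype=np.int8))
        merged = intersect_datasets(a, b)
        assert merged.n_snps == 3  # A/T site dropped, two private in a dropped
        assert merged.merge_log["n_ambiguous_dropped"] == 1

    def test_no_overlap_errors(self):
        a = simple_ds([[0]], [("A", "G")], "a")
        b = simple_ds([[0, 0]], [("A", "T"), ("C", "G")], "b")
        with pytest.raises(ValueError, match="no overlapping"):
            intersect_datasets(a, b)


class TestPseudoHaploidize:
    def test_homozygotes_fixed_and_deterministic(self, rng):
        ds = random_dataset(rng, n_ind=10, n_snps=30)
        out1 = pseudo_haploidize(ds, seed=11)
        out2 = pseudo_haploidize(ds, seed=11)
        assert np.array_equal(out1.geno, out2.geno)
        hom = np.isin(ds.geno, (0, 2, MISSING))
        assert np.array_equal(out1.geno[hom], ds.geno[hom])
        assert np.isin(out1.geno, (0, 2, MISSING)).all()

    def test_het_split_is_fair(self):
        ds = simple_ds(np.ones((1, 1), dtype=int), [("A", "G")])
        big = Dataset(
            ds.snps,
            make_ind_table([f"i{k}" for k in range(10_000)], ["p"] * 10_000),
            np.ones((10_000, 1), dtype=np.int8),
        )
        out = pseudo_haploidize(big, seed=3)
        frac2 = (out.geno == 2).mean()
        assert abs(frac2 - 0.5) < 0.015

    def test_preserves_expected_frequency(self, rng):
        # haploidization is mean-preserving: |mean(out)/2 - mean(in)/2|
        # within 3 conditional SEs (only het sites are randomized)
        n = 10_000
        p = np.array([0.1, 0.3, 0.5, 0.8])
        geno = rng.binomial(2, p, size=(n, 4)).astype(np.int8)
        snps = make_snp_table(np.ones(4, dtype=int), [100, 200, 300, 400],
                              [0.0, 0.01, 0.02, 0.03])
        ds = Dataset(snps, make_ind_table([f"i{k}" for k in range(n)], ["p"] * n), geno)
        out = pseudo_haploidize(ds, seed=9)
        diff = np.abs(out.geno.mean(axis=0) - geno.mean(axis=0)) / 2
        n_het = (geno == 1).sum(axis=0)
        cond_se = np.sqrt(n_het) / (2 * n)
        assert np.all(diff < 3 * cond_se)
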