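"""Variant-file parsing: VCF/MAF/Bambino readers and coverage summaries."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varcna.variant_io import (
    NORMAL_TUMOR,
    TUMOR_NORMAL,
    RunConfig,
    VariantFileError,
    VariantRecord,
    chrom_sort_key,
    read_bambino,
    read_maf,
    read_paired_vcf,
    snv_counts,
    write_bambino,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def write_vcf(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadPairedVcf:
    def test_ad_extraction_and_total(self, tmp_path):
        # tumor allele depths (30, 30) -> mutant 30, total 60
        p = write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:30,30\t0/0:40,10\n")
        (rec,) = list(read_paired_vcf(p, TUMOR_NORMAL))
        assert (rec.tumor_mutant, rec.tumor_total) == (30, 60)
        assert (rec.normal_mutant, rec.normal_total) == (10, 50)
        assert rec.chrom == "1"  # "chr" prefix normalized away

    def test_sample_order_swaps_assignment(self, tmp_path):
        p = write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:30,30\t0/0:40,10\n")
        (tn,) = list(read_paired_vcf(p, TUMOR_NORMAL))
        (nt,) = list(read_paired_vcf(p, NORMAL_TUMOR))
        assert (nt.tumor_mutant, nt.tumor_total) == (tn.normal_mutant, tn.normal_total)
        assert (nt.normal_mutant, nt.normal_total) == (tn.tumor_mutant, tn.tumor_total)

    def test_multiallelic_and_indel_rows_skipped(self, tmp_path):
        body = (
            "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT:AD\t0/1:10,5,5\t0/1:10,5,5\n"
            "1\t200\t.\tAT\tA\t.\tPASS\t.\tGT:AD\t0/1:10,5\t0/1:10,5\n"
            "1\t300\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:10,5\t0/1:10,5\n"
        )
        recs = list(read_paired_vcf(write_vcf(tmp_path, body), TUMOR_NORMAL))
        assert [r.pos for r in recs] == [300]

    def test_single_sample_is_fatal(self, tmp_path):
        p = tmp_path / "one.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:30,30\n"
        )
        with pytest.raises(VariantFileError, match="two genotype columns"):
            list(read_paired_vcf(p, TUMOR_NORMAL))

    def test_no_depth_anywhere_is_fatal(self, tmp_path):
        p = tmp_path / "nodp.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        )
        with pytest.raises(VariantFileError, match="allele-depth"):
            list(read_paired_vcf(p, TUMOR_NORMAL))


class TestBambino:
    def test_direct_mapping(self, tmp_path):
        p = tmp_path / "v.txt"
        p.write_text("chr1\t1000\tA\tG\t30\t60\t25\t50\n")
        (r,) = list(read_bambino(p))
        assert r == VariantRecord("1", 1000, "A", "G", 30, 60, 25, 50)

    def test_empty_file_gives_empty_stream(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert list(read_bambino(p)) == []

    def test_negative_count_row_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1\t1000\tA\tG\t-3\t60\t25\t50\n1\t2000\tA\tG\t3\t60\t25\t50\n")
        assert [r.pos for r in read_bambino(p)] == [2000]

    def test_round_trip(self, tmp_path):
        recs = [
            VariantRecord("1", 1000, "A", "G", 30, 60, 25, 50),
            VariantRecord("X", 5, "C", "T", 0, 12, 6, 12),
        ]
        p = tmp_path / "rt.txt"
        write_bambino(recs, p)
        assert list(read_bambino(p)) == recs


class TestMaf:
    HEADER = (
        "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
        "Tumor_Seq_Allele2\tt_alt_count\tt_ref_count\tn_alt_count\tn_ref_count\n"
    )

    def test_count_sum_convention(self, tmp_path):
        p = tmp_path / "v.maf"
        p.write_text(self.HEADER + "G1\t1\t1000\tA\tG\t12\t28\t5\t45\n")
        (r,) = list(read_maf(p))
        assert (r.tumor_mutant, r.tumor_total) == (12, 40)
        assert (r.normal_mutant, r.normal_total) == (5, 50)

    def test_header_only(self, tmp_path):
        p = tmp_path / "h.maf"
        p.write_text(self.HEADER)
        assert list(read_maf(p)) == []

    def test_row_missing_counts_skipped(self, tmp_path):
        p = tmp_path / "m.maf"
        p.write_text(self.HEADER + "G1\t1\t1000\tA\tG\t12\t.\t5\t45\n")
        assert list(read_maf(p)) == []

    def test_missing_column_fatal(self, tmp_path):
        p = tmp_path / "bad.maf"
        p.write_text("Chromosome\tStart_Position\n1\t5\n")
        with pytest.raises(VariantFileError, match="t_alt_count"):
            list(read_maf(p))


class TestSnvCounts:
    def test_mean_and_median(self):
        recs = [
            VariantRecord("1", i, "A", "G", 0, 10, 0, d)
            for i, d in [(1, 40), (2, 50), (3, 60)]
        ]
        _, summary = snv_counts(recs)
        assert summary.mean == 50 and summary.median == 50

    def test_single_record(self):
        recs, summary = snv_counts([VariantRecord("1", 1, "A", "G", 0, 10, 0, 37)])
        assert summary.mean == summary.median == 37

    def test_empty_stream_fatal(self):
        with pytest.raises(VariantFileError, match="no usable variants"):
            snv_counts([])

    def test_duplicate_positions_collapse(self):
        recs = [
            VariantRecord("1", 5, "A", "G", 0, 10, 0, 10),
            VariantRecord("1", 5, "A", "T", 0, 10, 0, 20),
        ]
        out, _ = snv_counts(recs)
        assert len(out) == 1

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.sampled_from(["1", "2", "10", "X", "chr3"]), st.integers(1, 10_000)),
            min_size=1,
            max_size=40,
        )
    )
    def test_output_totally_ordered(self, sites):
        recs = [VariantRecord(c, p, "A", "G", 0, 10, 5, 10) for c, p in sites]
        out, _ = snv_counts(recs)
        keys = [(chrom_sort_key(r.chrom), r.pos) for r in out]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)  # no duplicate positions


def test_run_config_invariants():
    with pytest.raises(ValueError):
        RunConfig(min_factor=3.0, max_factor=0.2)
    with pytest.raises(ValueError):
        RunConfig(window_size=0)
    with pytest.raises(ValueError):
        RunConfig(sample_order="sideways")
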