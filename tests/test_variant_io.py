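"""VCF/BED/TSV I/O: field mapping, coordinate conventions, roundtrips."""

import numpy as np
import pandas as pd
import pytest

from lineage_clockwork.variant_io import (
    FormatError,
    RegionSet,
    read_depth_table,
    read_regions,
    read_sample_sheet,
    read_variant_calls,
    write_depth_table,
    write_regions,
    write_sample_sheet,
    write_vcf,
)
from conftest import make_calls


class TestRegions:
    def test_half_open_arithmetic(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("Y\t0\t100\n")
        rs = read_regions(bed)["Y"]
        assert rs.total_length == 100
        assert rs.contains([0, 99, 100]).tolist() == [True, True, False]

    def test_overlapping_intervals_merged(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("Y\t0\t100\nY\t50\t150\n")
        rs = read_regions(bed)["Y"]
        assert rs.intervals == [(0, 150)]
        assert rs.total_length == 150

    def test_empty_file_gives_empty_regions(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("")
        assert read_regions(bed) == {}
        assert RegionSet("Y").total_length == 0

    def test_start_ge_end_reports_line_number(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("Y\t0\t100\nY\t200\t200\n")
        with pytest.raises(FormatError, match=":2:"):
            read_regions(bed)

    def test_chr_prefix_normalized(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chrY\t0\t10\nchrX\t5\t25\n")
        rs = read_regions(bed)
        assert set(rs) == {"X", "Y"}
        assert rs["X"].total_length == 20


class TestVCF:
    def test_ad_field_mapping(self, tmp_path):
        calls = make_calls([("S1", "Y", 101, "A", "T", 12, 5)])
        path = tmp_path / "s1.vcf"
        write_vcf(calls, path, "S1", {"Y": 1000})
        back = read_variant_calls(path)
        assert back.iloc[0]["ref_reads"] == 12
        assert back.iloc[0]["alt_reads"] == 5
        assert back.iloc[0]["depth"] == 17
        assert back.iloc[0]["chrom"] == "Y"

    def test_roundtrip_100_records(self, tmp_path):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(10_000, size=100, replace=False)) + 1
        refs = np.array(list("ACGT"))[rng.integers(0, 4, 100)]
        alts = [("T" if r != "T" else "A") for r in refs]
        rr = rng.integers(0, 30, 100)
        ar = rng.integers(1, 30, 100)
        calls = make_calls(
            [("S1", "Y", int(p), r, a, int(x), int(y))
             for p, r, a, x, y in zip(pos, refs, alts, rr, ar)]
        )
        path = tmp_path / "s1.vcf"
        write_vcf(calls, path, "S1", {"Y": 20_000})
        back = read_variant_calls(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), calls.reset_index(drop=True),
            check_dtype=False,
        )

    def test_single_value_ad_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=Y>\n"
            '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "Y\t5\t.\tA\tT\t.\tPASS\t.\tAD\t3\n"
        )
        with pytest.raises(FormatError, match="AD"):
            read_variant_calls(path)

    def test_missing_ad_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=Y>\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "Y\t5\t.\tA\tT\t.\tPASS\t.\tDP\t9\n"
        )
        with pytest.raises(FormatError, match="missing AD"):
            read_variant_calls(path)

    def test_multiallelic_records_split_and_indels_skipped(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=Y>\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "Y\t5\t.\tA\tT,G\t.\tPASS\t.\tAD\t10,4,2\n"
            "Y\t9\t.\tAT\tA\t.\tPASS\t.\tAD\t7,3\n"
        )
        calls = read_variant_calls(path)
        assert len(calls) == 2  # the indel is dropped
        assert calls["alt"].tolist() == ["T", "G"]
        assert calls["alt_reads"].tolist() == [4, 2]
        assert (calls["ref_reads"] == 10).all()

    def test_unknown_sample_rejected_against_sheet(self, tmp_path):
        calls = make_calls([("S1", "Y", 101, "A", "T", 12, 5)])
        path = tmp_path / "s1.vcf"
        write_vcf(calls, path, "S1")
        sheet = pd.DataFrame(
            {"sample_id": ["OTHER"], "haplogroup": ["H1"], "batch": ["b"]}
        )
        with pytest.raises(FormatError, match="S1"):
            read_variant_calls(path, sheet)


class TestTables:
    def test_sample_sheet_roundtrip_and_validation(self, tmp_path):
        df = pd.DataFrame(
            {"sample_id": ["a", "b"], "haplogroup": ["H1", "H2"], "batch": ["x", "x"]}
        )
        p = tmp_path / "s.tsv"
        write_sample_sheet(df, p)
        pd.testing.assert_frame_equal(read_sample_sheet(p), df)
        (tmp_path / "bad.tsv").write_text("sample_id\thap\na\tH1\n")
        with pytest.raises(FormatError, match="missing columns"):
            read_sample_sheet(tmp_path / "bad.tsv")

    def test_depth_table_roundtrip(self, tmp_path):
        df = pd.DataFrame({
            "chrom": ["Y", "Y"], "start": [0, 100], "end": [100, 200],
            "sample_id": ["s", "s"], "depth": [30, 31],
        })
        p = tmp_path / "d.tsv"
        write_depth_table(df, p)
        pd.testing.assert_frame_equal(read_depth_table(p), df)

    def test_gzipped_bed_accepted(self, tmp_path):
        import gzip

        p = tmp_path / "r.bed.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("Y\t0\t50\n")
        assert read_regions(p)["Y"].total_length == 50


def test_rendered_cohort_files_roundtrip(small_cohort, tmp_path):
    """End-to-end file I/O: write a cohort, read one sample's VCF back."""
    from lineage_clockwork.synthetic import write_cohort

    cfg, truth, rendered = small_cohort
    write_cohort(rendered, truth, tmp_path)
    sid = rendered.sample_sheet["sample_id"].iloc[0]
    back = read_variant_calls(tmp_path / "vcf" / f"{sid}.vcf")
    orig = rendered.calls[rendered.calls["sample_id"] == sid]
    orig = orig.sort_values(["chrom", "pos"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(
        back[["chrom", "pos", "ref", "alt", "ref_reads", "alt_reads", "depth"]],
        orig[["chrom", "pos", "ref", "alt", "ref_reads", "alt_reads", "depth"]],
        check_dtype=False,
    )
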