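"""Annotation parsing, read quality filtering, pileup construction, VCF I/O."""

import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asepipe.annotation_io import (
    AnnotationError,
    TranscriptModel,
    load_annotation,
    merge_intervals,
    read_filter,
    read_snp_vcf,
    write_snp_vcf,
    build_pileups,
    SampleLibrary,
)
from asepipe.snp_discovery import SnpCall


class TestTranscriptModel:
    def test_summed_exon_length(self):
        tx = TranscriptModel("t1", "chr1", "+", ((100, 200), (300, 400)))
        assert tx.summed_exon_length == 200

    def test_rejects_overlapping_exons(self):
        with pytest.raises(AnnotationError):
            TranscriptModel("t1", "chr1", "+", ((0, 100), (50, 150)))

    def test_rejects_empty_interval(self):
        with pytest.raises(AnnotationError):
            TranscriptModel("t1", "chr1", "+", ((100, 100),))

    def test_merge_intervals_unions_overlaps(self):
        assert merge_intervals([(0, 100), (50, 150)]) == ((0, 150),)
        assert merge_intervals([(300, 400), (100, 200)]) == ((100, 200), (300, 400))


class TestLoadAnnotation:
    def test_bed12_block_sum(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text(
            "chr1\t100\t400\ttx1\t0\t+\t100\t400\t0\t2\t100,100\t0,200\n"
        )
        (model,) = load_annotation(bed)
        assert model.transcript_id == "tx1"
        assert model.exons == ((100, 200), (300, 400))
        assert model.summed_exon_length == 200

    def test_gff3_overlapping_exons_merged(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t1\t150\t.\t+\t.\tID=tx1\n"
            "chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=e1;Parent=tx1\n"
            "chr1\tsrc\texon\t51\t150\t.\t+\t.\tID=e2;Parent=tx1\n"
        )
        (model,) = load_annotation(gff)
        assert model.exons == ((0, 150),)
        assert model.summed_exon_length == 150

    def test_empty_file_returns_empty(self, tmp_path, caplog):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        assert load_annotation(bed) == []

    def test_malformed_bed_names_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t100\n")
        with pytest.raises(AnnotationError, match="bad.bed:1"):
            load_annotation(bed)


class TestReadFilter:
    def test_discards_above_30pct_low_quality(self):
        quals = [10] * 31 + [38] * 69
        keep, _, _ = read_filter(quals)
        assert not keep

    def test_boundary_is_strict(self):
        quals = [10] * 30 + [38] * 70
        keep, _, _ = read_filter(quals)
        assert keep

    def test_end_trimming(self):
        quals = [10, 10, 10] + [38] * 95 + [10, 10]
        keep, start, end = read_filter(quals)
        assert keep
        assert (start, end) == (3, 98)

    def test_missing_qualities_discarded_by_default(self):
        keep, _, _ = read_filter(None)
        assert not keep
        keep, _, _ = read_filter(None, missing_quality_policy="keep")
        assert keep

    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=1, max_size=150))
    @settings(max_examples=200, deadline=None)
    def test_keep_iff_low_fraction_at_most_30pct(self, quals):
        keep, start, end = read_filter(quals)
        n_low = sum(q < 20 for q in quals)
        assert keep == (n_low <= 0.3 * len(quals))
        if keep:
            # surviving window exists and its edges are high quality
            assert 0 <= start <= end <= len(quals)
            if start < end:
                assert quals[start] >= 20 and quals[end - 1] >= 20


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"


def _write_sam(path, records):
    path.write_text(SAM_HEADER + "".join(r + "\n" for r in records))


def _tx():
    return TranscriptModel("tx1", "chr1", "+", ((100, 160), (220, 260)))


class TestBuildPileups:
    def test_unanimous_column_and_quality_split(self, tmp_path):
        # 3 reads over exon1; one has a low-quality base at offset 5
        reads = []
        for i in range(2):
            reads.append(f"r{i}\t0\tchr1\t101\t60\t10M\t*\t0\t0\tCCCCCCCCCC\t{'I' * 10}")
        reads.append("r2\t0\tchr1\t101\t60\t10M\t*\t0\t0\tCCCCCCCCCC\tIIIII,IIII")
        sam = tmp_path / "a.sam"
        _write_sam(sam, reads)
        pset = build_pileups([sam], [_tx()], SampleLibrary("s", "parent1", "tillering"))
        col = pset.columns[("tx1", 100)]
        assert col.counts["C"] == 3 and col.other_count == 0
        low_col = pset.columns[("tx1", 105)]
        assert low_col.counts["C"] == 2 and low_col.other_count == 1
        # count conservation at every column
        for col in pset.columns.values():
            assert col.depth + col.other_count == 3

    def test_intron_only_read_contributes_nothing(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, ["r0\t0\tchr1\t171\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t" + "I" * 10])
        pset = build_pileups([sam], [_tx()], SampleLibrary("s", "parent1", "tillering"))
        assert pset.columns == {}
        assert pset.library.total_mapped_reads == 1  # retained, just off-exon

    def test_secondary_and_unmapped_excluded(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(
            sam,
            [
                "r0\t256\tchr1\t101\t60\t10M\t*\t0\t0\tCCCCCCCCCC\t" + "I" * 10,
                "r1\t4\t*\t0\t0\t*\t*\t0\t0\tCCCCCCCCCC\t" + "I" * 10,
            ],
        )
        pset = build_pileups([sam], [_tx()], SampleLibrary("s", "parent1", "tillering"))
        assert pset.columns == {}
        assert pset.library.total_mapped_reads == 0

    def test_chromosome_mismatch_is_hard_error(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:scaffold9\tLN:1000\n")
        with pytest.raises(AnnotationError, match="scaffold9"):
            build_pileups([sam], [_tx()], SampleLibrary("s", "parent1", "tillering"))

    def test_spliced_read_skips_intron(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(
            sam,
            ["r0\t0\tchr1\t156\t60\t5M60N5M\t*\t0\t0\tGGGGGGGGGG\t" + "I" * 10],
        )
        pset = build_pileups([sam], [_tx()], SampleLibrary("s", "parent1", "tillering"))
        assert set(pset.columns) == {("tx1", p) for p in [155, 156, 157, 158, 159, 220, 221, 222, 223, 224]}


class TestVcfRoundTrip:
    def test_write_then_read_reproduces_calls(self, tmp_path):
        snps = [
            SnpCall("tx1", "chr1", 999, "C", "T", 15, 12, 31.5, frozenset({"tillering", "heading"})),
            SnpCall("tx2", "chr1", 42, "G", "A", 20, 30, 60.0, frozenset({"tillering", "heading"})),
        ]
        path = tmp_path / "out.vcf"
        write_snp_vcf(snps, path)
        text = path.read_text()
        assert "##fileformat=VCFv4.2" in text
        assert "\t1000\t" in text  # 0-based 999 -> POS 1000
        assert "DP1=15;DP2=12" in text
        back = sorted(read_snp_vcf(path), key=lambda s: s.pos)
        orig = sorted(snps, key=lambda s: s.pos)
        for a, b in zip(orig, back):
            assert (a.transcript_id, a.chrom, a.pos, a.allele_p1, a.allele_p2) == (
                b.transcript_id, b.chrom, b.pos, b.allele_p1, b.allele_p2)
            assert (a.depth_p1, a.depth_p2) == (b.depth_p1, b.depth_p2)
            assert a.stages_detected == b.stages_detected
            assert b.qual == pytest.approx(a.qual, abs=0.01)

    def test_empty_set_yields_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_snp_vcf([], path)
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        with pysam.VariantFile(str(path)) as vcf:
            assert list(vcf) == []
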