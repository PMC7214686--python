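"""Parsing, coordinate conversion and round-trip behavior of the readers."""

from pathlib import Path

import pytest
from hypothesis import given, settings, strategies as st

from promdens import (GenomicInterval, ParseError, TssRecord, attach_tpm,
                      dedup_tss, read_peaks, read_tpm, read_tss,
                      write_intervals)
from promdens.genome_io import check_chrom_compatibility


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPeaks:
    def test_narrowpeak_field_mapping(self, tmp_path):
        p = _write(tmp_path, "a.narrowPeak",
                   "chr1\t100\t600\tpeak_1\t80\t.\t5.1\t9.2\t7.7\t250\n")
        ps = read_peaks(p, format="narrowPeak", mark="H3K4me3")
        iv = ps.intervals[0]
        assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr1", 100, 600, "peak_1")
        assert iv.score == 80

    def test_empty_interval_rejected_with_line_number(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chr1\t50\t80\nchr1\t100\t100\n")
        with pytest.raises(ParseError, match="line 2"):
            read_peaks(p)

    def test_bed3_autoname(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chrX\t0\t50\n")
        iv = read_peaks(p).intervals[0]
        assert (iv.chrom, iv.start, iv.end) == ("chrX", 0, 50)
        assert iv.name  # auto-generated

    @pytest.mark.parametrize("fmt,ncols", [("narrowPeak", 10), ("broadPeak", 9)])
    def test_encode_column_counts_enforced(self, tmp_path, fmt, ncols):
        line = "\t".join(["chr1", "10", "20"] + ["."] * (ncols - 4))  # one short
        p = _write(tmp_path, "a.pk", line + "\n")
        with pytest.raises(ParseError, match="line 1"):
            read_peaks(p, format=fmt)

    def test_non_integer_coordinates(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chr1\tten\t20\n")
        with pytest.raises(ParseError, match="non-integer"):
            read_peaks(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_peaks(tmp_path / "nope.bed")

    def test_output_sorted(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chr2\t5\t10\nchr1\t100\t200\nchr1\t5\t10\n")
        ps = read_peaks(p)
        keys = [(iv.chrom, iv.start) for iv in ps]
        assert keys == sorted(keys)


class TestReadTss:
    GTF = (
        'chr1\tsrc\ttranscript\t1000\t2000\t.\t+\t.\tgene_id "g1"; transcript_id "t_plus";\n'
        'chr1\tsrc\ttranscript\t1000\t2000\t.\t-\t.\tgene_id "g1"; transcript_id "t_minus";\n'
        'chr1\tsrc\texon\t1000\t1200\t.\t+\t.\tgene_id "g1"; transcript_id "t_plus";\n'
    )

    def test_gtf_strand_aware_tss(self, tmp_path):
        recs = read_tss(_write(tmp_path, "a.gtf", self.GTF), format="gtf")
        by_id = {r.transcript_id: r for r in recs}
        assert by_id["t_plus"].position == 999  # 1-based start -> 0-based
        assert by_id["t_minus"].position == 1999  # 1-based end -> 0-based

    def test_tss_inside_transcript_span(self, tmp_path):
        for rec in read_tss(_write(tmp_path, "a.gtf", self.GTF), format="gtf"):
            assert 999 <= rec.position < 2000

    def test_missing_strand_rejected_with_identifier(self, tmp_path):
        gtf = 'chr1\tsrc\ttranscript\t10\t20\t.\t.\t.\ttranscript_id "tx_bad";\n'
        with pytest.raises(ParseError, match="tx_bad"):
            read_tss(_write(tmp_path, "b.gtf", gtf), format="gtf")

    def test_duplicate_coordinates_merged(self, tmp_path):
        gtf = (
            'chr1\tsrc\ttranscript\t500\t900\t.\t+\t.\ttranscript_id "txA";\n'
            'chr1\tsrc\ttranscript\t500\t800\t.\t+\t.\ttranscript_id "txB";\n'
        )
        recs = read_tss(_write(tmp_path, "c.gtf", gtf), format="gtf")
        assert len(recs) == 1
        assert recs[0].transcript_id == "txA,txB"

    def test_bed6_minus_strand_position(self, tmp_path):
        bed = "chr1\t100\t101\ttxm\t.\t-\n"
        rec = read_tss(_write(tmp_path, "t.bed", bed), format="bed6")[0]
        assert rec.position == 100
        assert rec.strand == "-"


class TestTpm:
    def test_basic_mapping(self, tmp_path):
        p = _write(tmp_path, "t.tsv", "target_id\ttpm\nENSMUST0001\t12.5\n")
        assert read_tpm(p) == {"ENSMUST0001": 12.5}

    def test_negative_tpm_error(self, tmp_path):
        p = _write(tmp_path, "t.tsv", "target_id\ttpm\ntx1\t-1\n")
        with pytest.raises(ParseError, match="negative"):
            read_tpm(p)

    def test_duplicate_id_error(self, tmp_path):
        p = _write(tmp_path, "t.tsv", "target_id\ttpm\ntx1\t1\ntx1\t2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_tpm(p)

    def test_empty_table(self, tmp_path):
        p = _write(tmp_path, "t.tsv", "target_id\ttpm\n")
        assert read_tpm(p) == {}

    def test_absent_transcript_stays_unquantified(self):
        recs = [TssRecord("chr1", 10, "+", "txA")]
        out = attach_tpm(recs, {"other": 5.0})
        assert out[0].tpm is None

    def test_merged_tss_tpm_sum_and_max(self):
        recs = dedup_tss([TssRecord("chr1", 10, "+", "txA"),
                          TssRecord("chr1", 10, "+", "txB")])
        table = {"txA": 2.0, "txB": 3.0}
        assert attach_tpm(recs, table, combine="sum")[0].tpm == 5.0
        assert attach_tpm(recs, table, combine="max")[0].tpm == 3.0


class TestRoundTrip:
    @settings(max_examples=30, deadline=None)
    @given(st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2", "chrX"]),
                  st.integers(0, 10_000), st.integers(1, 500),
                  st.sampled_from(["+", "-", "."])),
        min_size=0, max_size=50))
    def test_bed_write_read_identity(self, rows):
        import tempfile
        tmp = Path(tempfile.mkdtemp())
        intervals = [
            GenomicInterval(c, s, s + w, name=f"iv{i}", strand=strand)
            for i, (c, s, w, strand) in enumerate(rows)]
        path = tmp / "x.bed"
        write_intervals(intervals, path)
        back = read_peaks(path).intervals
        expect = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        assert [(iv.chrom, iv.start, iv.end, iv.name, iv.strand) for iv in back] \
            == [(iv.chrom, iv.start, iv.end, iv.name, iv.strand) for iv in expect]

    def test_empty_set_roundtrip(self, tmp_path):
        path = tmp_path / "e.bed"
        write_intervals([], path)
        assert read_peaks(path).intervals == ()


def test_chrom_mismatch_warns():
    with pytest.warns(UserWarning, match="unshared"):
        unshared = check_chrom_compatibility({"chr1"}, {"1"})
    assert unshared == {"chr1", "1"}


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10)
    with pytest.raises(ValueError):
        TssRecord("chr1", 5, ".", "tx")
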