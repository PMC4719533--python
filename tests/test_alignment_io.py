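"""FASTA/QUAL, FASTQ, SAM and TCS parsing and writing."""

import io

import pytest

from poolvar.alignment_io import (
    QualSequence,
    TcsRecord,
    annotate_fasta_titles,
    read_fasta_qual,
    read_fastq,
    read_sam,
    read_tcs,
    write_fasta_qual,
    write_fastq,
    write_sam,
    write_tcs,
)
from poolvar.caller import VariantCall
from poolvar.errors import FormatError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFastaQual:
    def test_direct_transcription(self, tmp_path):
        f = _write(tmp_path, "c.fasta", ">c1 a contig\nACGT\n")
        q = _write(tmp_path, "c.qual", ">c1 a contig\n30 30 30 30\n")
        (rec,) = read_fasta_qual(f, q)
        assert (rec.id, rec.bases, rec.quals) == ("c1", "ACGT", [30] * 4)
        assert rec.description == "a contig"

    def test_length_mismatch_names_record(self, tmp_path):
        f = _write(tmp_path, "c.fasta", ">c1\nACGT\n")
        q = _write(tmp_path, "c.qual", ">c1\n30 30 30\n")
        with pytest.raises(FormatError, match="c1"):
            read_fasta_qual(f, q)

    def test_id_order_mismatch_rejected(self, tmp_path):
        f = _write(tmp_path, "c.fasta", ">a\nAC\n>b\nGT\n")
        q = _write(tmp_path, "c.qual", ">b\n1 1\n>a\n2 2\n")
        with pytest.raises(FormatError, match="order mismatch"):
            read_fasta_qual(f, q)

    def test_wrapped_input_accepted(self, tmp_path):
        f = _write(tmp_path, "c.fasta", ">c1\nACGT\nACGT\n")
        q = _write(tmp_path, "c.qual", ">c1\n10 11 12 13\n14 15 16 17\n")
        (rec,) = read_fasta_qual(f, q)
        assert rec.bases == "ACGTACGT"
        assert rec.quals == list(range(10, 18))

    def test_write_read_write_is_byte_identical(self, tmp_path, small_truth):
        seqs = small_truth.contigs
        f1, q1 = tmp_path / "a.fasta", tmp_path / "a.qual"
        write_fasta_qual(seqs, f1, q1)
        back = read_fasta_qual(f1, q1)
        f2, q2 = tmp_path / "b.fasta", tmp_path / "b.qual"
        write_fasta_qual(back, f2, q2)
        assert f1.read_bytes() == f2.read_bytes()
        assert q1.read_bytes() == q2.read_bytes()

    def test_hundred_record_round_trip(self, tmp_path):
        seqs = [
            QualSequence(f"s{i:03d}", "ACGTN"[: 1 + i % 5] * 3,
                         [i % 60] * (3 * (1 + i % 5)), f"desc {i}")
            for i in range(100)
        ]
        f, q = tmp_path / "r.fasta", tmp_path / "r.qual"
        write_fasta_qual(seqs, f, q)
        assert read_fasta_qual(f, q) == seqs


class TestFastq:
    def test_round_trip(self, tmp_path):
        seqs = [QualSequence("r1", "ACGT", [2, 40, 0, 93], "x")]
        p = tmp_path / "r.fastq"
        write_fastq(seqs, p)
        assert read_fastq(p) == seqs


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:8\n"
CONTIG = QualSequence("c1", "ACGTACGT", [40] * 8)


def _sam(tmp_path, body):
    return _write(tmp_path, "in.sam", SAM_HEADER + body)


class TestSam:
    def test_identity_alignment(self, tmp_path):
        p = _sam(tmp_path, "r1\t0\tc1\t1\t60\t4M\t*\t0\t0\tACGT\t????\n")
        (read,) = read_sam(p, [CONTIG])
        assert (read.start, read.aligned_bases) == (0, "ACGT")
        assert read.aligned_quals == (30, 30, 30, 30)
        assert read.strand == "+"

    def test_insertion_not_projected(self, tmp_path):
        # 2M 1I 2M: the inserted base is not a contig column
        p = _sam(tmp_path, "r1\t0\tc1\t1\t60\t2M1I2M\t*\t0\t0\tACGGT\t?????\n")
        (read,) = read_sam(p, [CONTIG])
        assert read.aligned_bases == "ACGT"
        assert read.end == 4

    def test_deletion_projects_gap(self, tmp_path):
        p = _sam(tmp_path, "r1\t16\tc1\t1\t60\t2M2D2M\t*\t0\t0\tACAC\t????\n")
        (read,) = read_sam(p, [CONTIG])
        assert read.aligned_bases == "AC--AC"
        assert read.aligned_quals[2] is None
        assert read.strand == "-"

    def test_soft_clip_excluded(self, tmp_path):
        p = _sam(tmp_path, "r1\t0\tc1\t3\t60\t2S3M1S\t*\t0\t0\tTTGTAC\t??????\n")
        (read,) = read_sam(p, [CONTIG])
        assert (read.start, read.aligned_bases) == (2, "GTA")

    def test_unmapped_skipped(self, tmp_path):
        p = _sam(tmp_path, "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t????\n")
        assert read_sam(p, [CONTIG]) == []

    def test_header_contig_mismatch(self, tmp_path):
        p = _sam(tmp_path, "")
        with pytest.raises(FormatError, match="length"):
            read_sam(p, [QualSequence("c1", "ACGT", [1] * 4)])

    def test_read_past_contig_end_rejected(self, tmp_path):
        p = _sam(tmp_path, "r1\t0\tc1\t7\t60\t4M\t*\t0\t0\tACGT\t????\n")
        with pytest.raises(FormatError, match="r1"):
            read_sam(p, [CONTIG])

    def test_projection_matches_brute_force_walk(self, tmp_path, small_truth):
        """Projected spans agree with an independent CIGAR re-walk."""
        sam = tmp_path / "fix.sam"
        write_sam(small_truth.reads[:50], small_truth.contigs, sam)
        reads = read_sam(sam, small_truth.contigs)
        raw = [
            line.split("\t")
            for line in sam.read_text().splitlines()
            if not line.startswith("@")
        ][:50]
        for read, fields in zip(reads, raw):
            bases, qpos = [], 0
            num = ""
            for ch in fields[5]:
                if ch.isdigit():
                    num += ch
                    continue
                n = int(num)
                num = ""
                if ch in "M=X":
                    bases.extend(fields[9][qpos:qpos + n])
                    qpos += n
                elif ch in "DN":
                    bases.extend("-" * n)
                elif ch in "IS":
                    qpos += n
            assert read.start == int(fields[3]) - 1
            assert read.aligned_bases == "".join(bases)

    def test_sam_round_trip_preserves_reads(self, tmp_path, small_truth):
        sam = tmp_path / "rt.sam"
        write_sam(small_truth.reads, small_truth.contigs, sam)
        assert read_sam(sam, small_truth.contigs) == small_truth.reads


class TestTcs:
    def _records(self):
        return [
            TcsRecord("c1", 1, "A", 10, {"A": 10, "C": 0, "G": 0, "T": 0, "gap": 0},
                      {"A": 30, "C": 0, "G": 0, "T": 0}),
            TcsRecord("c1", 2, "C", 12, {"A": 2, "C": 9, "G": 0, "T": 0, "gap": 1},
                      {"A": 20, "C": 35, "G": 0, "T": 0}),
        ]

    def test_empty_gives_header_only(self):
        buf = io.StringIO()
        write_tcs([], buf)
        lines = buf.getvalue().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_single_column_serialization(self):
        buf = io.StringIO()
        write_tcs(self._records()[:1], buf)
        data = buf.getvalue().splitlines()[1]
        assert data == "c1\t1\tA\t10\t10\t0\t0\t0\t0\t30\t0\t0\t0"

    def test_round_trip(self, tmp_path):
        p = tmp_path / "x.tcs"
        write_tcs(self._records(), p)
        assert read_tcs(p) == self._records()

    def test_unsorted_rejected(self):
        with pytest.raises(FormatError, match="sorted"):
            write_tcs(list(reversed(self._records())), io.StringIO())


def _call(contig, pos, major="A", minor="T"):
    return VariantCall(contig, pos, major, minor, 14, 6, 75.0, 72.0, 20)


class TestAnnotateTitles:
    def test_token_convention(self):
        contig = QualSequence("c1", "A" * 200, [40] * 200)
        (out,) = annotate_fasta_titles([contig], [_call("c1", 122)])
        assert out.description == "SNP:123:A/T"

    def test_contigs_without_calls_excluded(self):
        contigs = [QualSequence("c1", "ACGT", [1] * 4),
                   QualSequence("c2", "ACGT", [1] * 4)]
        out = annotate_fasta_titles(contigs, [_call("c2", 0)])
        assert [o.id for o in out] == ["c2"]

    def test_tokens_sorted_by_position(self):
        contig = QualSequence("c1", "A" * 50, [40] * 50)
        calls = [_call("c1", 30), _call("c1", 5), _call("c1", 12)]
        (out,) = annotate_fasta_titles([contig], calls)
        assert out.description == "SNP:6:A/T SNP:13:A/T SNP:31:A/T"

    def test_position_beyond_contig_rejected(self):
        contig = QualSequence("c1", "ACGT", [1] * 4)
        with pytest.raises(FormatError, match="beyond"):
            annotate_fasta_titles([contig], [_call("c1", 10)])
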