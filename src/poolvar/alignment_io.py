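"""On-disk format handling: FASTA, paired FASTA.QUAL, FASTQ, SAM and TCS.

The assembly arrives as contig consensus sequences (FASTA) with paired
per-base qualities (FASTA.QUAL, whitespace-separated integers) or as FASTQ
(Phred+33), plus read-to-contig alignments in SAM.  The per-column summary
("TCS") written after SNP calling is a tab-separated dialect defined by this
package: one line per contig column carrying the consensus base, total
covering reads, the five A/C/G/T/gap counts and the four per-base mean
qualities (rounded half-up to integers).

Coordinates are 0-based half-open in memory; every serialized position
(TCS lines, SNP title tokens) is 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pysam
from Bio import SeqIO

from poolvar.errors import FormatError

_VALID_BASES = frozenset("ACGTN")

# CIGAR operator codes -> (consumes_query, consumes_reference)
_CIGAR_CONSUMES = {
    0: (True, True),   # M
    1: (True, False),  # I
    2: (False, True),  # D
    3: (False, True),  # N
    4: (True, False),  # S
    5: (False, False),  # H
    6: (False, False),  # P
    7: (True, True),   # =
    8: (True, True),   # X
}


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass
class QualSequence:
    """A nucleotide sequence with one integer quality per base."""

    id: str
    bases: str
    quals: list[int]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        self.bases = self.bases.upper()
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise FormatError(
                f"sequence {self.id}: unexpected characters {sorted(bad)}"
            )
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"length mismatch for {self.id}: "
                f"{len(self.bases)} bases vs {len(self.quals)} qualities"
            )
        if any(q < 0 for q in self.quals):
            raise FormatError(f"sequence {self.id}: negative quality value")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        if not self.quals:
            return 0.0
        return sum(self.quals) / len(self.quals)


@dataclass
class AlignedRead:
    """A mapped read projected onto contig columns.

    ``aligned_bases`` holds one symbol per covered contig column ('-' where
    the read has a deletion); ``aligned_quals`` runs parallel with ``None``
    at gaps.  Read insertions relative to the contig are not columns and are
    dropped by the projection; soft-clipped ends are excluded.
    """

    read_id: str
    contig_id: str
    start: int
    aligned_bases: str
    aligned_quals: tuple[int | None, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"read {self.read_id}: negative start")
        if len(self.aligned_bases) != len(self.aligned_quals):
            raise FormatError(
                f"read {self.read_id}: bases/quals length mismatch"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"read {self.read_id}: bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        """One past the last covered contig column."""
        return self.start + len(self.aligned_bases)


@dataclass
class TcsRecord:
    """One per-column line of the TCS summary (1-based position)."""

    contig_id: str
    position: int
    consensus_base: str
    total_coverage: int
    per_base_counts: dict[str, int] = field(default_factory=dict)  # A,C,G,T,gap
    per_base_mean_quals: dict[str, int] = field(default_factory=dict)  # A,C,G,T

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError("TCS positions are 1-based")
        if self.total_coverage != sum(self.per_base_counts.values()):
            raise FormatError(
                f"TCS {self.contig_id}:{self.position}: coverage "
                f"{self.total_coverage} != sum of per-base counts"
            )


# ---------------------------------------------------------------------------
# FASTA + QUAL / FASTQ
# ---------------------------------------------------------------------------

def _split_title(record) -> tuple[str, str]:
    desc = record.description
    if desc.startswith(record.id):
        desc = desc[len(record.id):].lstrip()
    return record.id, desc


def read_fasta_qual(fasta_source, qual_source) -> list[QualSequence]:
    """Read paired FASTA and FASTA.QUAL files into QualSequence records.

    Records must appear in the same order in both files; a mismatched id or
    an unequal base/quality length raises :class:`FormatError` naming the
    offending record.
    """
    seqs = list(SeqIO.parse(str(fasta_source), "fasta"))
    quals = list(SeqIO.parse(str(qual_source), "qual"))
    if len(seqs) != len(quals):
        raise FormatError(
            f"FASTA has {len(seqs)} records but QUAL has {len(quals)}"
        )
    out = []
    for s, q in zip(seqs, quals):
        if s.id != q.id:
            raise FormatError(
                f"record order mismatch: FASTA {s.id!r} vs QUAL {q.id!r}"
            )
        scores = q.letter_annotations["phred_quality"]
        if len(s.seq) != len(scores):
            raise FormatError(
                f"length mismatch for {s.id}: {len(s.seq)} bases vs "
                f"{len(scores)} qualities"
            )
        rid, desc = _split_title(s)
        out.append(QualSequence(rid, str(s.seq), list(scores), desc))
    return out


def read_fastq(source) -> list[QualSequence]:
    """Read a Phred+33 FASTQ file into QualSequence records."""
    out = []
    for rec in SeqIO.parse(str(source), "fastq"):
        rid, desc = _split_title(rec)
        out.append(
            QualSequence(
                rid, str(rec.seq), list(rec.letter_annotations["phred_quality"]), desc
            )
        )
    return out


def _open_sink(sink, mode="w"):
    if hasattr(sink, "write"):
        return sink, False
    return open(sink, mode), True


def write_fasta_qual(seqs: Sequence[QualSequence], fasta_sink, qual_sink) -> None:
    """Write paired FASTA/QUAL; one sequence line per record (stable form)."""
    fh, close_f = _open_sink(fasta_sink)
    qh, close_q = _open_sink(qual_sink)
    try:
        for s in seqs:
            title = f"{s.id} {s.description}".rstrip()
            fh.write(f">{title}\n{s.bases}\n")
            qh.write(f">{title}\n{' '.join(map(str, s.quals))}\n")
    finally:
        if close_f:
            fh.close()
        if close_q:
            qh.close()


def write_fastq(seqs: Sequence[QualSequence], sink) -> None:
    """Write Phred+33 FASTQ."""
    fh, close = _open_sink(sink)
    try:
        for s in seqs:
            title = f"{s.id} {s.description}".rstrip()
            qual = "".join(chr(min(q, 93) + 33) for q in s.quals)
            fh.write(f"@{title}\n{s.bases}\n+\n{qual}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(sam_source, contigs: Sequence[QualSequence]) -> list[AlignedRead]:
    """Read a SAM file and project each mapped record onto contig columns.

    The header's sequence dictionary must match ``contigs`` by name and
    length.  Unmapped records are skipped.  CIGAR operators M/=/X/I/D/S/H/N/P
    are supported; insertions and soft clips never appear in the projection.
    """
    by_id = {c.id: c for c in contigs}
    reads: list[AlignedRead] = []
    try:
        af = pysam.AlignmentFile(str(sam_source), "r", check_sq=False)
    except ValueError as exc:
        raise FormatError(f"cannot parse SAM {sam_source}: {exc}") from exc
    with af:
        for name, length in zip(af.references, af.lengths):
            if name not in by_id:
                raise FormatError(f"SAM header names unknown contig {name!r}")
            if length != len(by_id[name]):
                raise FormatError(
                    f"SAM header length {length} for {name} != contig "
                    f"length {len(by_id[name])}"
                )
        for lineno, rec in enumerate(af, start=1):
            if rec.is_unmapped:
                continue
            rname = rec.reference_name
            if rname not in by_id:
                raise FormatError(
                    f"SAM line {lineno}: reference {rname!r} not in contigs"
                )
            try:
                read = _project(rec, lineno)
            except FormatError:
                raise
            except Exception as exc:  # malformed CIGAR / fields
                raise FormatError(f"SAM line {lineno}: {exc}") from exc
            if read.end > len(by_id[rname]):
                raise FormatError(
                    f"read {read.read_id} projects beyond contig {rname} "
                    f"({read.end} > {len(by_id[rname])})"
                )
            reads.append(read)
    return reads


def _project(rec, lineno: int) -> AlignedRead:
    seq = rec.query_sequence
    quals = rec.query_qualities
    if seq is None:
        raise FormatError(f"SAM line {lineno}: record has no sequence")
    if quals is None:
        raise FormatError(f"SAM line {lineno}: record has no base qualities")
    cigar = rec.cigartuples
    if not cigar:
        raise FormatError(f"SAM line {lineno}: mapped record without CIGAR")
    bases: list[str] = []
    bquals: list[int | None] = []
    qpos = 0
    for op, length in cigar:
        if op not in _CIGAR_CONSUMES:
            raise FormatError(f"SAM line {lineno}: unsupported CIGAR op {op}")
        cq, cr = _CIGAR_CONSUMES[op]
        if cq and cr:  # M/=/X
            bases.extend(seq[qpos:qpos + length].upper())
            bquals.extend(quals[qpos:qpos + length])
            qpos += length
        elif cr:       # D/N: contig column with no read base
            bases.extend("-" * length)
            bquals.extend([None] * length)
        elif cq:       # I/S: read bases that are not contig columns
            qpos += length
    return AlignedRead(
        read_id=rec.query_name,
        contig_id=rec.reference_name,
        start=rec.reference_start,
        aligned_bases="".join(bases),
        aligned_quals=tuple(bquals),
        strand="-" if rec.is_reverse else "+",
    )


def write_sam(reads: Sequence[AlignedRead], contigs: Sequence[QualSequence], sink) -> None:
    """Write reads as single-end SAM with an @SQ header built from contigs.

    The CIGAR is reconstructed from the column projection (runs of bases
    become M, runs of gaps become D).
    """
    fh, close = _open_sink(sink)
    try:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in contigs:
            fh.write(f"@SQ\tSN:{c.id}\tLN:{len(c)}\n")
        for r in reads:
            cigar = []
            for sym, _, n in _runs(r.aligned_bases):
                cigar.append(f"{n}{'D' if sym == '-' else 'M'}")
            seq = r.aligned_bases.replace("-", "")
            qual = "".join(
                chr(min(q, 93) + 33) for q in r.aligned_quals if q is not None
            )
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.read_id}\t{flag}\t{r.contig_id}\t{r.start + 1}\t60\t"
                f"{''.join(cigar)}\t*\t0\t0\t{seq}\t{qual}\n"
            )
    finally:
        if close:
            fh.close()


def _runs(s: str) -> Iterable[tuple[str, int, int]]:
    """Yield (gap-or-base marker, start, length) for runs of gap vs base."""
    i = 0
    while i < len(s):
        j = i
        is_gap = s[i] == "-"
        while j < len(s) and (s[j] == "-") == is_gap:
            j += 1
        yield ("-" if is_gap else "M", i, j - i)
        i = j


# ---------------------------------------------------------------------------
# TCS
# ---------------------------------------------------------------------------

_TCS_HEADER = (
    "# contig\tposition\tconsensus\tcoverage\t"
    "A\tC\tG\tT\tgap\tmeanQ_A\tmeanQ_C\tmeanQ_G\tmeanQ_T\n"
)


def write_tcs(records: Sequence[TcsRecord], sink) -> None:
    """Write per-column summaries, one tab-separated line per column.

    Records must already be sorted by (contig_id, position); sorting is the
    caller's contract and unsorted input raises.
    """
    keys = [(r.contig_id, r.position) for r in records]
    if keys != sorted(keys):
        raise FormatError("TCS records must be sorted by (contig, position)")
    fh, close = _open_sink(sink)
    try:
        fh.write(_TCS_HEADER)
        for r in records:
            counts = [r.per_base_counts.get(b, 0) for b in "ACGT"] + [
                r.per_base_counts.get("gap", 0)
            ]
            mq = [r.per_base_mean_quals.get(b, 0) for b in "ACGT"]
            fh.write(
                f"{r.contig_id}\t{r.position}\t{r.consensus_base}\t"
                f"{r.total_coverage}\t" + "\t".join(map(str, counts)) + "\t"
                + "\t".join(map(str, mq)) + "\n"
            )
    finally:
        if close:
            fh.close()


def read_tcs(source) -> list[TcsRecord]:
    """Read a TCS file written by :func:`write_tcs`."""
    records = []
    path = Path(source) if not hasattr(source, "read") else None
    fh: IO = open(path) if path else source
    try:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 13:
                raise FormatError(f"TCS line {lineno}: expected 13 fields")
            contig, pos, cons, cov = parts[0], parts[1], parts[2], parts[3]
            counts = dict(zip(["A", "C", "G", "T", "gap"], map(int, parts[4:9])))
            mq = dict(zip("ACGT", map(int, parts[9:13])))
            records.append(
                TcsRecord(contig, int(pos), cons, int(cov), counts, mq)
            )
    finally:
        if path:
            fh.close()
    return records


def tcs_from_pileup(column, contig: QualSequence) -> TcsRecord:
    """Summarize a pileup column as a TCS line.

    Total coverage counts reads contributing a base or a deletion; N
    observations stay outside both tallies, mirroring the pileup's own
    bookkeeping.
    """
    counts = {b: column.base_counts.get(b, 0) for b in "ACGT"}
    counts["gap"] = column.gap_count
    mq = {}
    for b in "ACGT":
        qs = column.base_quals.get(b, [])
        mq[b] = _round_half_up(sum(qs) / len(qs)) if qs else 0
    return TcsRecord(
        contig_id=column.contig_id,
        position=column.position + 1,
        consensus_base=contig.bases[column.position],
        total_coverage=column.depth_R + column.gap_count,
        per_base_counts=counts,
        per_base_mean_quals=mq,
    )


# ---------------------------------------------------------------------------
# SNP-annotated FASTA titles
# ---------------------------------------------------------------------------

def annotate_fasta_titles(contigs: Sequence[QualSequence], calls) -> list[QualSequence]:
    """Return only SNP-bearing contigs, with one title token per call.

    Each description gains tokens of the form ``SNP:<1-based-pos>:<V1>/<V2>``
    in ascending position order.
    """
    by_contig: dict[str, list] = {}
    index = {c.id: c for c in contigs}
    for call in calls:
        if call.contig_id not in index:
            raise FormatError(f"call references unknown contig {call.contig_id!r}")
        if call.position >= len(index[call.contig_id]):
            raise FormatError(
                f"call at {call.contig_id}:{call.position + 1} beyond contig end"
            )
        by_contig.setdefault(call.contig_id, []).append(call)
    out = []
    for c in contigs:
        if c.id not in by_contig:
            continue
        tokens = [
            f"SNP:{call.position + 1}:{call.major_base}/{call.minor_base}"
            for call in sorted(by_contig[c.id], key=lambda x: x.position)
        ]
        desc = " ".join(([c.description] if c.description else []) + tokens)
        out.append(QualSequence(c.id, c.bases, list(c.quals), desc))
    return out
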