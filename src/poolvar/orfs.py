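"""Fitting SNPs into open reading frames.

Each SNP-bearing contig is scanned in all six frames for ORFs — by default
maximal stop-free stretches (stop-to-stop, standard genetic code TAA/TAG/TGA),
since EST contigs are frequently 5'-truncated and an ATG requirement would
discard real coding context; ATG-to-stop is available as a mode.  The SNP's
placement inside its best ORF gives the frame, codon position and flank
lengths used to judge how much conserved context surrounds the site.

Coordinates of reverse-frame ORFs are reported on the forward strand,
0-based half-open; ``orf_seq`` and ``snp_offset`` follow the reading
direction of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from poolvar.alignment_io import QualSequence
from poolvar.caller import VariantCall
from poolvar.errors import PoolvarError

STOP_CODONS = {"TAA", "TAG", "TGA"}
FRAME_ORDER = (1, 2, 3, -1, -2, -3)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MIN_ORF_LEN = 90  # 30 codons
ORF_MODES = ("stop-to-stop", "atg-to-stop")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class OrfAnnotation:
    """A SNP placed inside its best ORF."""

    contig_id: str
    frame: int                # +1..+3 forward, -1..-3 reverse
    orf_start: int            # forward-strand, 0-based half-open
    orf_end: int
    orf_seq: str              # in reading direction (revcomp for -frames)
    snp_offset: int           # 0-based position of the SNP within orf_seq
    codon_position: int       # 1, 2 or 3
    left_flank: int           # bases from ORF start to the SNP (reading dir)
    right_flank: int          # bases from the SNP to ORF end (reading dir)
    call: VariantCall

    def __post_init__(self) -> None:
        length = self.orf_end - self.orf_start
        if length <= 0 or length % 3:
            raise PoolvarError("ORF length must be a positive multiple of 3")
        if self.left_flank + self.right_flank + 1 != length:
            raise PoolvarError("flank lengths inconsistent with ORF length")


def find_orfs(
    seq: str, min_len: int = DEFAULT_MIN_ORF_LEN, mode: str = "stop-to-stop"
) -> list[tuple[int, int, int]]:
    """Scan all six frames for ORFs of at least ``min_len`` bases.

    Returns (frame, start, end) triples with forward-strand coordinates and
    lengths that are multiples of 3; stop codons are never included.
    """
    if min_len < 3 or min_len % 3:
        raise PoolvarError("min_len must be >= 3 and a multiple of 3")
    if mode not in ORF_MODES:
        raise PoolvarError(f"unknown ORF mode {mode!r}")
    seq = seq.upper()
    n = len(seq)
    out: list[tuple[int, int, int]] = []
    for frame in FRAME_ORDER:
        strand_seq = seq if frame > 0 else reverse_complement(seq)
        offset = abs(frame) - 1
        for s, e in _frame_orfs(strand_seq, offset, min_len, mode):
            if frame > 0:
                out.append((frame, s, e))
            else:
                out.append((frame, n - e, n - s))
    return out


def _frame_orfs(seq: str, offset: int, min_len: int, mode: str):
    """Stop-free codon runs (strand-local coordinates) of one frame."""
    n_codons = (len(seq) - offset) // 3
    run_start = None
    for i in range(n_codons + 1):
        pos = offset + 3 * i
        codon = seq[pos:pos + 3] if i < n_codons else None
        if codon is None or codon in STOP_CODONS:
            if run_start is not None:
                yield from _emit_run(seq, run_start, pos, min_len, mode)
                run_start = None
        elif run_start is None:
            run_start = pos


def _emit_run(seq: str, start: int, end: int, min_len: int, mode: str):
    if mode == "atg-to-stop":
        atg = next(
            (p for p in range(start, end, 3) if seq[p:p + 3] == "ATG"), None
        )
        if atg is None:
            return
        start = atg
    if end - start >= min_len:
        yield (start, end)


def place_snps(
    calls: Sequence[VariantCall],
    contigs: Sequence[QualSequence],
    min_len: int = DEFAULT_MIN_ORF_LEN,
    mode: str = "stop-to-stop",
) -> tuple[list[OrfAnnotation], list[VariantCall]]:
    """Assign each call to the single best ORF containing its position.

    Best = longest; ties broken by the most centered SNP, then by frame
    order +1..+3,-1..-3.  The major allele is substituted at every call
    position before scanning, so the reported ORF carries the consensus
    variant.  Calls contained in no ORF come back in a separate list, not
    dropped.
    """
    index = {c.id: c for c in contigs}
    by_contig: dict[str, list[VariantCall]] = {}
    for call in calls:
        if call.contig_id not in index:
            raise PoolvarError(f"call references unknown contig {call.contig_id!r}")
        by_contig.setdefault(call.contig_id, []).append(call)

    annotations: list[OrfAnnotation] = []
    no_orf: list[VariantCall] = []
    for contig_id, contig_calls in sorted(by_contig.items()):
        seq = list(index[contig_id].bases)
        for call in contig_calls:
            seq[call.position] = call.major_base
        seq = "".join(seq)
        orfs = find_orfs(seq, min_len=min_len, mode=mode)
        for call in sorted(contig_calls, key=lambda c: c.position):
            best = _best_orf(orfs, call.position)
            if best is None:
                no_orf.append(call)
                continue
            frame, s, e = best
            if frame > 0:
                orf_seq = seq[s:e]
                off = call.position - s
            else:
                orf_seq = reverse_complement(seq[s:e])
                off = e - 1 - call.position
            annotations.append(
                OrfAnnotation(
                    contig_id=contig_id,
                    frame=frame,
                    orf_start=s,
                    orf_end=e,
                    orf_seq=orf_seq,
                    snp_offset=off,
                    codon_position=off % 3 + 1,
                    left_flank=off,
                    right_flank=len(orf_seq) - off - 1,
                    call=call,
                )
            )
    return annotations, no_orf


def _best_orf(orfs, position: int):
    containing = [o for o in orfs if o[1] <= position < o[2]]
    if not containing:
        return None

    def key(o):
        frame, s, e = o
        length = e - s
        off = (position - s) if frame > 0 else (e - 1 - position)
        centering = abs(off - (length - 1) / 2)
        return (-length, centering, FRAME_ORDER.index(frame))

    return min(containing, key=key)


def write_orf_fasta(annotations: Sequence[OrfAnnotation], sink) -> None:
    """Write ORF sequences with frame and SNP placement in the title.

    Title convention: ``<contig>_ORF<k> frame:<±f> SNP:<1-based-offset>:<V1>/<V2>``
    with k a per-contig running index.
    """
    close = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w")
        close = True
    try:
        counters: dict[str, int] = {}
        for a in annotations:
            counters[a.contig_id] = counters.get(a.contig_id, 0) + 1
            k = counters[a.contig_id]
            sink.write(
                f">{a.contig_id}_ORF{k} frame:{a.frame:+d} "
                f"SNP:{a.snp_offset + 1}:{a.call.major_base}/{a.call.minor_base}\n"
                f"{a.orf_seq}\n"
            )
    finally:
        if close:
            sink.close()
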