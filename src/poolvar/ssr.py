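"""Native microsatellite (SSR) detection.

A tandem-repeat scorer in the etandem tradition: a candidate region of unit
length k is compared against the consensus motif obtained by per-phase
majority vote, and scored as (matching bases) − (mismatching bases) over
the whole span.  A region is a maximal non-extendable tract: it ends
exactly where the period-k self-match breaks, so reported tracts are
perfect against their consensus (substitutions or indels split a repeat
into separate tracts rather than diluting one).  Regions of different unit
lengths that overlap are reduced to the highest-scoring one (ties: smaller
unit, then leftmost).  Motifs are reported in canonical rotation — the
lexicographically smallest — so phase-shifted duplicates of the same tract
never appear twice.

Defaults (unit 1–6, minimum score 12, i.e. at least six perfect dinucleotide
units) suit genotyping-oriented SSR mining in EST contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from poolvar.errors import PoolvarError

DEFAULT_MIN_UNIT = 1
DEFAULT_MAX_UNIT = 6
DEFAULT_MIN_SCORE = 12


@dataclass
class SsrHit:
    contig_id: str
    start: int          # 0-based half-open on the forward strand
    end: int
    motif: str          # canonical (lexicographically smallest) rotation
    unit_len: int
    n_units: int        # complete units in the span (partial unit excluded)
    score: int          # matches - mismatches vs the tiled consensus
    identity_pct: float

    def __post_init__(self) -> None:
        if self.end - self.start < 2 * self.unit_len:
            raise PoolvarError("SSR span shorter than two units")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise PoolvarError("identity must be a percentage")


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _consensus(seq: str, start: int, end: int, k: int) -> str:
    """Per-phase majority base over [start, end); ties go to A<C<G<T."""
    motif = []
    for phase in range(k):
        counts: dict[str, int] = {}
        for pos in range(start + phase, end, k):
            counts[seq[pos]] = counts.get(seq[pos], 0) + 1
        motif.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(motif)


def _score(seq: str, start: int, end: int, k: int) -> tuple[int, int, str]:
    """(score, matches, phase-0 consensus motif) for a region."""
    motif = _consensus(seq, start, end, k)
    matches = sum(
        1 for pos in range(start, end) if seq[pos] == motif[(pos - start) % k]
    )
    span = end - start
    return 2 * matches - span, matches, motif


def find_ssrs(
    seq: str,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_score: int = DEFAULT_MIN_SCORE,
    contig_id: str = "",
) -> list[SsrHit]:
    """Detect tandem repeats of unit length min_unit..max_unit in ``seq``."""
    if not 1 <= min_unit <= max_unit:
        raise PoolvarError("need 1 <= min_unit <= max_unit")
    if min_score < 1:
        raise PoolvarError("min_score must be >= 1")
    seq = seq.upper()
    candidates: list[SsrHit] = []
    for k in range(min_unit, max_unit + 1):
        candidates.extend(_candidates_for_unit(seq, k, min_score, contig_id))
    return _reduce_overlaps(candidates)


def _candidates_for_unit(seq: str, k: int, min_score: int, contig_id: str):
    n = len(seq)
    # Self-match at lag k: a run of r consecutive matches means seq[s : s+r+k)
    # repeats with period k.
    regions: list[tuple[int, int]] = []
    i = 0
    while i < n - k:
        if seq[i] == seq[i + k]:
            j = i
            while j < n - k and seq[j] == seq[j + k]:
                j += 1
            if j - i >= k:  # at least two full units in the span
                regions.append((i, j + k))
            i = j + 1
        else:
            i += 1

    hits = []
    for s, e in regions:
        score, matches, motif = _score(seq, s, e, k)
        if score < min_score:
            continue
        span = e - s
        hits.append(
            SsrHit(
                contig_id=contig_id,
                start=s,
                end=e,
                motif=canonical_rotation(motif),
                unit_len=k,
                n_units=span // k,
                score=score,
                identity_pct=100.0 * matches / span,
            )
        )
    return hits


def _reduce_overlaps(hits: list[SsrHit]) -> list[SsrHit]:
    """Keep the best hit wherever spans overlap (score desc, unit asc, left)."""
    chosen: list[SsrHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.unit_len, h.start)):
        if all(hit.end <= c.start or hit.start >= c.end for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: (h.contig_id, h.start))
    return chosen


def scan_contigs(
    contigs,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_score: int = DEFAULT_MIN_SCORE,
) -> list[SsrHit]:
    """Run the SSR scan over every contig consensus."""
    hits: list[SsrHit] = []
    for c in contigs:
        hits.extend(
            find_ssrs(c.bases, min_unit, max_unit, min_score, contig_id=c.id)
        )
    return hits


def write_ssr_table(hits: Sequence[SsrHit], sink) -> None:
    """Tab-separated SSR report with 1-based inclusive coordinates."""
    close = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w")
        close = True
    try:
        sink.write("# contig\tstart\tend\tmotif\tunit_len\tunits\tscore\tidentity_pct\n")
        for h in hits:
            sink.write(
                f"{h.contig_id}\t{h.start + 1}\t{h.end}\t{h.motif}\t"
                f"{h.unit_len}\t{h.n_units}\t{h.score}\t{h.identity_pct:.1f}\n"
            )
    finally:
        if close:
            sink.close()
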