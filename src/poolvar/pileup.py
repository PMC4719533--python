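"""Per-contig-column base/quality tallies (the pileup).

A column's depth ``R`` counts only reads contributing a real base (A/C/G/T)
to the column: deletions are tallied separately in ``gap_count`` and N
observations in ``n_count``, because the detection criterion reasons about
base variants and counting non-bases toward coverage would inflate depth
toward calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from poolvar.alignment_io import AlignedRead, QualSequence
from poolvar.errors import PoolvarError


@dataclass
class PileupColumn:
    contig_id: str
    position: int  # 0-based
    base_counts: dict[str, int] = field(default_factory=dict)
    base_quals: dict[str, list[int]] = field(default_factory=dict)
    gap_count: int = 0
    n_count: int = 0

    @property
    def depth_R(self) -> int:
        """Reads covering this column with a base (the criterion's ΣR)."""
        return sum(self.base_counts.values())

    def validate(self) -> None:
        for b, n in self.base_counts.items():
            if n != len(self.base_quals.get(b, [])):
                raise PoolvarError(
                    f"{self.contig_id}:{self.position}: count/qual mismatch for {b}"
                )
        if any(q < 0 for qs in self.base_quals.values() for q in qs):
            raise PoolvarError("negative quality in pileup column")


def build_pileup(reads: Sequence[AlignedRead], contig: QualSequence) -> list[PileupColumn]:
    """Tally reads into one PileupColumn per contig position.

    Zero-depth columns are materialized too, so the result always has
    exactly ``len(contig)`` entries in positional order.
    """
    columns = [PileupColumn(contig.id, i) for i in range(len(contig))]
    for read in reads:
        if read.contig_id != contig.id:
            raise PoolvarError(
                f"read {read.read_id} maps to {read.contig_id}, not {contig.id}"
            )
        if read.start < 0 or read.end > len(contig):
            raise PoolvarError(
                f"read {read.read_id} projects outside contig bounds "
                f"[{read.start}, {read.end}) vs length {len(contig)}"
            )
        for offset, (base, qual) in enumerate(
            zip(read.aligned_bases, read.aligned_quals)
        ):
            col = columns[read.start + offset]
            if base == "-":
                col.gap_count += 1
            elif base == "N":
                col.n_count += 1
            else:
                col.base_counts[base] = col.base_counts.get(base, 0) + 1
                col.base_quals.setdefault(base, []).append(
                    0 if qual is None else qual
                )
    return columns


def rank_variants(column: PileupColumn) -> list[tuple[str, int, float]]:
    """Order a column's observed bases for the detection criterion.

    Bases with count > 0 sorted by count descending; ties broken by higher
    mean quality, then by fixed base order A<C<G<T, so the ranking is
    deterministic even on exactly balanced columns.
    """
    entries = []
    for base, count in column.base_counts.items():
        if count <= 0:
            continue
        quals = column.base_quals.get(base, [])
        mean_q = sum(quals) / len(quals) if quals else 0.0
        entries.append((base, count, mean_q))
    entries.sort(key=lambda e: (-e[1], -e[2], e[0]))
    return entries
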