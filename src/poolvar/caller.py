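"""The pooled-sample SNP detection criterion.

A column is a putative SNP when all four conjuncts hold for the two most
frequent base variants V1 and V2:

    ΣR ≥ C    and    ΣV2 ≥ v_min    and    Q̄_V1 ≥ Q_min    and    Q̄_V2 ≥ Q_min

Defaults: C = 15, v_min = 20 % of C (resolved with a ceiling, so rounding
never weakens the threshold), Q_min = 70 on the input's own quality scale —
a scale chosen for assembler-adjusted qualities, which exceed raw Phred
maxima; no rescaling is performed.  Variants beyond V2 never block or
create a call: a tri-allelic column is judged on its top two variants only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from poolvar.errors import ConfigError
from poolvar.pileup import PileupColumn, rank_variants

DEFAULT_MIN_COVERAGE = 15
DEFAULT_MIN_VARIANTS_FRAC = 0.20
DEFAULT_MIN_QUALITY = 70.0


@dataclass(frozen=True)
class DetectionConfig:
    """Criterion parameters C, v_min and Q_min.

    ``min_variants`` is an absolute count when set; otherwise
    ``min_variants_frac`` expresses v_min as a fraction of C.
    """

    min_coverage: int = DEFAULT_MIN_COVERAGE
    min_variants: int | None = None
    min_variants_frac: float | None = DEFAULT_MIN_VARIANTS_FRAC
    min_quality: float = DEFAULT_MIN_QUALITY

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be a positive integer")
        if (self.min_variants is None) == (self.min_variants_frac is None):
            raise ConfigError(
                "exactly one of min_variants / min_variants_frac must be set"
            )
        if self.min_variants is not None and self.min_variants < 1:
            raise ConfigError("min_variants must be >= 1")
        if self.min_variants_frac is not None and not (
            0.0 < self.min_variants_frac <= 1.0
        ):
            raise ConfigError("min_variants_frac must be in (0, 1]")
        if self.min_quality < 0:
            raise ConfigError("min_quality must be non-negative")


@dataclass(frozen=True)
class VariantCall:
    """An accepted SNP: the column's top two variants with their evidence."""

    contig_id: str
    position: int  # 0-based
    major_base: str
    minor_base: str
    count_major: int
    count_minor: int
    mean_qual_major: float
    mean_qual_minor: float
    depth: int


def resolve_vmin(config: DetectionConfig) -> int:
    """Resolve v_min to an absolute count (ceiling for fractional values)."""
    if config.min_variants is not None:
        return config.min_variants
    vmin = math.ceil(config.min_variants_frac * config.min_coverage)
    if vmin < 1:
        raise ConfigError("resolved min_variants is < 1")
    return vmin


def evaluate_column(
    column: PileupColumn, config: DetectionConfig
) -> Optional[VariantCall]:
    """Apply the four-conjunct criterion to one pileup column.

    Returns a VariantCall iff the column has at least two variant base
    types and every conjunct holds; otherwise None.  Total over valid
    columns — never raises.
    """
    ranked = rank_variants(column)
    if len(ranked) < 2:
        return None
    (b1, n1, q1), (b2, n2, q2) = ranked[0], ranked[1]
    vmin = resolve_vmin(config)
    if (
        column.depth_R >= config.min_coverage
        and n2 >= vmin
        and q1 >= config.min_quality
        and q2 >= config.min_quality
    ):
        return VariantCall(
            contig_id=column.contig_id,
            position=column.position,
            major_base=b1,
            minor_base=b2,
            count_major=n1,
            count_minor=n2,
            mean_qual_major=q1,
            mean_qual_minor=q2,
            depth=column.depth_R,
        )
    return None


def call_snps(
    columns: Sequence[PileupColumn], config: DetectionConfig | None = None
) -> list[VariantCall]:
    """Evaluate every column and return accepted calls sorted by locus."""
    config = config or DetectionConfig()
    calls = []
    for col in columns:
        call = evaluate_column(col, config)
        if call is not None:
            calls.append(call)
    calls.sort(key=lambda c: (c.contig_id, c.position))
    return calls
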