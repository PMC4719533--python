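"""Shared synthetic fixtures.

Everything is generated in memory or under tmp_path at test time; the
expensive pooled-panel assembly used by the recovery and monotonicity tests
is built once per session.
"""

from __future__ import annotations

import pytest

from poolvar.caller import DetectionConfig
from poolvar.fixtures import generate_assembly
from poolvar.pileup import build_pileup


@pytest.fixture(scope="session")
def small_truth():
    """A modest pooled-panel assembly with planted SNPs and SSRs."""
    return generate_assembly(
        n_contigs=4, contig_len=1500, depth=25, n_snps=12,
        minor_fraction=0.3, error_rate=0.0, qual_model="constant:75",
        n_ssrs=1, seed=11,
    )


@pytest.fixture(scope="session")
def small_pileup(small_truth):
    """All pileup columns of the small assembly, in contig order."""
    cols = []
    for contig in small_truth.contigs:
        reads = [r for r in small_truth.reads if r.contig_id == contig.id]
        cols.extend(build_pileup(reads, contig))
    return cols


@pytest.fixture(scope="session")
def panel_truth():
    """The full-size pooled panel: 20 contigs x 2 kb, depth 30, 50 planted
    biallelic sites at minor fraction 0.3, no sequencing error, qualities
    above the default quality threshold."""
    return generate_assembly(
        n_contigs=20, contig_len=2000, depth=30, n_snps=50,
        minor_fraction=0.3, error_rate=0.0, qual_model="constant:75",
        seed=2016,
    )


@pytest.fixture(scope="session")
def panel_pileup(panel_truth):
    cols = []
    for contig in panel_truth.contigs:
        reads = [r for r in panel_truth.reads if r.contig_id == contig.id]
        cols.extend(build_pileup(reads, contig))
    return cols


@pytest.fixture
def default_config():
    return DetectionConfig()
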