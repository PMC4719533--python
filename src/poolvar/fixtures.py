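"""Deterministic synthetic pooled-panel assemblies with known truth.

The generator emulates the data this pipeline targets: a de-novo assembly
of reads pooled from many anonymous individuals.  Contigs are drawn
uniformly over ACGT; reads tile each contig to a target depth with random
start positions; at planted biallelic sites each read carries the minor
allele with probability ``minor_fraction`` (a pooled panel with the minor
allele at that population frequency); sequencing errors substitute a random
other base per base at ``error_rate``; qualities follow a constant or
two-level model.  Everything derives from one integer seed, so regeneration
is byte-identical.

The two-pool generator mirrors a merged pair of strain datasets with the
origin labels discarded: two haplotypes per contig differ at
Bernoulli(divergence) sites and reads are pooled without labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from poolvar.alignment_io import (
    AlignedRead,
    QualSequence,
    write_fasta_qual,
    write_sam,
)
from poolvar.errors import PoolvarError

_BASES = np.array(list("ACGT"))
CONSENSUS_QUAL = 90  # per-base quality assigned to contig consensus


class PlantedSnp(NamedTuple):
    contig_id: str
    position: int       # 0-based
    major: str
    minor: str
    minor_fraction: float


class PlantedSsr(NamedTuple):
    contig_id: str
    start: int          # 0-based
    motif: str
    units: int


@dataclass
class FixtureTruth:
    contigs: list[QualSequence]
    reads: list[AlignedRead]
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    planted_ssrs: list[PlantedSsr] = field(default_factory=list)
    seed: int = 0


def _parse_qual_model(qual_model: str):
    """'constant:<q>' or 'two-level:<high>:<low>:<low_fraction>'."""
    parts = qual_model.split(":")
    if parts[0] == "constant" and len(parts) == 2:
        q = int(parts[1])
        return lambda rng, n: np.full(n, q, dtype=int)
    if parts[0] == "two-level" and len(parts) == 4:
        hi, lo, frac = int(parts[1]), int(parts[2]), float(parts[3])
        return lambda rng, n: np.where(rng.random(n) < frac, lo, hi)
    raise PoolvarError(f"unrecognized qual_model {qual_model!r}")


def generate_assembly(
    n_contigs: int = 20,
    contig_len: int = 2000,
    depth: int = 30,
    n_snps: int = 50,
    minor_fraction: float = 0.3,
    error_rate: float = 0.0,
    qual_model: str = "constant:75",
    read_len: int = 400,
    n_ssrs: int = 0,
    seed: int = 0,
) -> FixtureTruth:
    """Simulate a pooled-panel assembly with planted SNPs (and SSRs).

    SNP sites are placed at least a read length away from contig ends so
    every site sees the full target depth; reads are generated already
    aligned, standing in for the external assembly stage.
    """
    if depth < 1:
        raise PoolvarError("depth must be >= 1")
    if not 0.0 < minor_fraction < 0.5:
        raise PoolvarError("minor_fraction must lie in (0, 0.5)")
    if not 0.0 <= error_rate < 0.1:
        raise PoolvarError("error_rate must lie in [0, 0.1)")
    if contig_len < 3 * read_len:
        raise PoolvarError("contig_len must be at least 3 read lengths")
    rng = np.random.default_rng(seed)
    qual_fn = _parse_qual_model(qual_model)

    contigs: list[QualSequence] = []
    seqs: dict[str, np.ndarray] = {}
    truth_ssrs: list[PlantedSsr] = []
    for ci in range(n_contigs):
        cid = f"contig{ci + 1:03d}"
        seq = rng.choice(_BASES, size=contig_len)
        for _ in range(n_ssrs):
            k = int(rng.integers(2, 5))
            units = int(rng.integers(8, 13))
            motif = "".join(rng.choice(_BASES, size=k))
            start = int(rng.integers(read_len, contig_len - read_len - k * units))
            tract = np.array(list(motif * units))
            seq[start:start + len(tract)] = tract
            truth_ssrs.append(PlantedSsr(cid, start, motif, units))
        seqs[cid] = seq
        contigs.append(
            QualSequence(cid, "".join(seq), [CONSENSUS_QUAL] * contig_len)
        )

    # plant biallelic sites, full-coverage zone only, unique positions
    truth_snps: list[PlantedSnp] = []
    site_minor: dict[tuple[str, int], str] = {}
    for _ in range(n_snps):
        cid = f"contig{int(rng.integers(n_contigs)) + 1:03d}"
        while True:
            pos = int(rng.integers(read_len, contig_len - read_len))
            if (cid, pos) not in site_minor:
                break
        major = seqs[cid][pos]
        minor = rng.choice(_BASES[_BASES != major])
        site_minor[(cid, pos)] = str(minor)
        truth_snps.append(
            PlantedSnp(cid, pos, str(major), str(minor), minor_fraction)
        )
    truth_snps.sort(key=lambda s: (s.contig_id, s.position))

    reads = _simulate_reads(
        rng, seqs, site_minor, minor_fraction, depth, read_len,
        error_rate, qual_fn,
    )
    return FixtureTruth(contigs, reads, truth_snps, truth_ssrs, seed)


def _simulate_reads(
    rng, seqs, site_minor, minor_fraction, depth, read_len, error_rate, qual_fn
) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    for cid, seq in seqs.items():
        contig_len = len(seq)
        sites = [(p, m) for (c, p), m in site_minor.items() if c == cid]
        n_reads = int(round(depth * contig_len / read_len))
        starts = rng.integers(0, contig_len - read_len + 1, size=n_reads)
        for ri, start in enumerate(sorted(map(int, starts))):
            bases = seq[start:start + read_len].copy()
            for pos, minor in sites:
                if start <= pos < start + read_len:
                    if rng.random() < minor_fraction:
                        bases[pos - start] = minor
            if error_rate > 0.0:
                err = rng.random(read_len) < error_rate
                for j in np.nonzero(err)[0]:
                    bases[j] = rng.choice(_BASES[_BASES != bases[j]])
            quals = qual_fn(rng, read_len)
            reads.append(
                AlignedRead(
                    read_id=f"{cid}_r{ri + 1:05d}",
                    contig_id=cid,
                    start=start,
                    aligned_bases="".join(bases),
                    aligned_quals=tuple(int(q) for q in quals),
                    strand="-" if rng.random() < 0.5 else "+",
                )
            )
    return reads


def generate_two_pool_mix(
    divergence: float,
    depth_per_pool: int = 20,
    n_contigs: int = 5,
    contig_len: int = 2000,
    read_len: int = 400,
    qual_model: str = "constant:75",
    seed: int = 0,
) -> FixtureTruth:
    """Two haplotypes per contig, reads pooled with origin labels discarded.

    Truth lists every site where the haplotypes differ, with the second
    haplotype's base as the minor allele at fraction 0.5 (balanced pools).
    """
    if not 0.0 <= divergence < 0.05:
        raise PoolvarError("divergence must lie in [0, 0.05)")
    rng = np.random.default_rng(seed)
    qual_fn = _parse_qual_model(qual_model)

    contigs: list[QualSequence] = []
    reads: list[AlignedRead] = []
    truth: list[PlantedSnp] = []
    for ci in range(n_contigs):
        cid = f"contig{ci + 1:03d}"
        hap_a = rng.choice(_BASES, size=contig_len)
        hap_b = hap_a.copy()
        for pos in np.nonzero(rng.random(contig_len) < divergence)[0]:
            hap_b[pos] = rng.choice(_BASES[_BASES != hap_a[pos]])
            truth.append(
                PlantedSnp(cid, int(pos), str(hap_a[pos]), str(hap_b[pos]), 0.5)
            )
        contigs.append(
            QualSequence(cid, "".join(hap_a), [CONSENSUS_QUAL] * contig_len)
        )
        ri = 0
        for hap in (hap_a, hap_b):
            n_reads = int(round(depth_per_pool * contig_len / read_len))
            starts = rng.integers(0, contig_len - read_len + 1, size=n_reads)
            for start in sorted(map(int, starts)):
                ri += 1
                quals = qual_fn(rng, read_len)
                reads.append(
                    AlignedRead(
                        read_id=f"{cid}_r{ri:05d}",
                        contig_id=cid,
                        start=start,
                        aligned_bases="".join(hap[start:start + read_len]),
                        aligned_quals=tuple(int(q) for q in quals),
                        strand="-" if rng.random() < 0.5 else "+",
                    )
                )
    truth.sort(key=lambda s: (s.contig_id, s.position))
    return FixtureTruth(contigs, reads, truth, [], seed)


def write_fixture(truth: FixtureTruth, outdir) -> dict[str, Path]:
    """Serialize a fixture as FASTA + QUAL + SAM + truth manifests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "contigs.fasta",
        "qual": outdir / "contigs.fasta.qual",
        "sam": outdir / "reads.sam",
        "truth_snps": outdir / "truth_snps.tsv",
        "truth_ssrs": outdir / "truth_ssrs.tsv",
    }
    write_fasta_qual(truth.contigs, paths["fasta"], paths["qual"])
    write_sam(truth.reads, truth.contigs, paths["sam"])
    with open(paths["truth_snps"], "w") as fh:
        fh.write("# contig\tposition\tmajor\tminor\tminor_fraction\n")
        for s in truth.planted_snps:
            fh.write(
                f"{s.contig_id}\t{s.position + 1}\t{s.major}\t{s.minor}\t"
                f"{s.minor_fraction}\n"
            )
    with open(paths["truth_ssrs"], "w") as fh:
        fh.write("# contig\tstart\tmotif\tunits\n")
        for r in truth.planted_ssrs:
            fh.write(f"{r.contig_id}\t{r.start + 1}\t{r.motif}\t{r.units}\n")
    return paths
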