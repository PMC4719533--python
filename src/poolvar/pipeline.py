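"""The 9-step orchestrator.

Steps:

  1  raw-data extraction (external converter; adapter, skipped by default)
  2  read cleaning — native length/mean-quality filter; contaminant
     screening is an external stage and is not performed here
  3  assembly (external assembler; adapter, skipped by default)
  4  pileup construction from the SAM alignments
  5  SNP calling; TCS summary + SNP-annotated contig FASTA
  6  ORF fitting of the called SNPs; SNP table and metrics HTML reports
     (protein-database search of the ORFs is an external stage)
  7  gene-ontology annotation (external; adapter, skipped by default)
  8  SSR detection (optional)
  9  packaging of result files into a zip archive

Optional and external steps never change the SNP call set.  The core path
has no randomness, so re-running an identical configuration reproduces
byte-identical result files (the timestamped run log is not a result file
and is excluded from the archive).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from poolvar import alignment_io as aio
from poolvar import ssr as ssr_mod
from poolvar.caller import call_snps, resolve_vmin
from poolvar.config import RunConfig
from poolvar.errors import StepError
from poolvar.metrics import (
    compute_metrics,
    package_results,
    render_metrics_report,
    render_snp_report,
)
from poolvar.orfs import place_snps, write_orf_fasta
from poolvar.pileup import build_pileup

log = logging.getLogger("poolvar")

EXTERNAL_STEPS = {
    1: "raw-data extraction (external converter)",
    3: "assembly (external assembler)",
    7: "gene-ontology annotation (external service)",
}
STEP_NAMES = {
    1: "extract", 2: "clean", 3: "assemble", 4: "pileup", 5: "snp-call",
    6: "characterize", 7: "ontology", 8: "ssr-scan", 9: "package",
}


@dataclass
class StepResult:
    number: int
    name: str
    status: str                      # done | skipped | external | failed
    detail: str = ""
    outputs: list[Path] = field(default_factory=list)


@dataclass
class RunSummary:
    steps: list[StepResult] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    output_dir: Path = Path(".")

    @property
    def ok(self) -> bool:
        return all(s.status != "failed" for s in self.steps)


def filter_reads(
    reads: Sequence[aio.QualSequence], min_len: int, min_mean_q: float
) -> tuple[list[aio.QualSequence], dict[str, int]]:
    """Keep reads with length >= min_len and mean quality >= min_mean_q.

    Discard reasons are tallied separately; a read failing both thresholds
    counts once, as short.
    """
    if min_len < 0 or min_mean_q < 0:
        raise StepError("filter thresholds must be >= 0")
    kept, discarded = [], {"short": 0, "low_quality": 0}
    for read in reads:
        if len(read) < min_len:
            discarded["short"] += 1
        elif read.mean_quality < min_mean_q:
            discarded["low_quality"] += 1
        else:
            kept.append(read)
    return kept, discarded


def run_pipeline(
    config: RunConfig,
    skip: Sequence[int] = (),
    only: Sequence[int] | None = None,
) -> RunSummary:
    """Execute the enabled steps in order and return the run summary."""
    config.validate()
    enabled = set(config.steps_enabled) - set(skip)
    if only is not None:
        enabled &= set(only)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    summary = RunSummary(output_dir=outdir)

    contigs = _load_contigs(config)
    reads = calls = columns_by_contig = annotations = None
    ssr_hits: list = []
    result_files: list[Path] = []

    with open(log_path, "w") as logfh:

        def note(msg: str) -> None:
            logfh.write(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}\n")
            log.info(msg)

        def record(step: int, status: str, detail: str = "", outputs=()):
            summary.steps.append(
                StepResult(step, STEP_NAMES[step], status, detail,
                           list(outputs))
            )
            note(f"step {step} ({STEP_NAMES[step]}): {status}"
                 + (f" — {detail}" if detail else ""))

        note(f"run started; enabled steps: {sorted(enabled)}")
        note(f"criterion: C={config.detection.min_coverage} "
             f"vmin={resolve_vmin(config.detection)} "
             f"Qmin={config.detection.min_quality:g}")

        for step in range(1, 10):
            if step not in enabled:
                record(step, "skipped", "disabled in configuration")
                continue
            if step in EXTERNAL_STEPS:
                record(step, "external", EXTERNAL_STEPS[step] + "; not run")
                continue
            try:
                if step == 2:
                    outs = _step_clean(config, outdir, summary, note)
                elif step == 4:
                    reads = aio.read_sam(config.reads_sam, contigs)
                    columns_by_contig = {
                        c.id: build_pileup(
                            [r for r in reads if r.contig_id == c.id], c
                        )
                        for c in contigs
                    }
                    summary.counts["reads"] = len(reads)
                    outs = []
                elif step == 5:
                    if columns_by_contig is None:
                        raise StepError("step 5 requires step 4")
                    calls, outs = _step_call(
                        config, outdir, contigs, columns_by_contig
                    )
                    summary.counts["snps"] = len(calls)
                elif step == 6:
                    if calls is None:
                        record(step, "skipped", "requires steps 4-5")
                        continue
                    # the metrics report counts SSRs, so scan ahead of time
                    # when the (later) SSR step is part of this run
                    if 8 in enabled and not ssr_hits:
                        ssr_hits = _scan_ssrs(config, contigs, summary)
                    annotations, outs = _step_characterize(
                        config, outdir, contigs, reads, calls, ssr_hits
                    )
                elif step == 8:
                    if not ssr_hits:
                        ssr_hits = _scan_ssrs(config, contigs, summary)
                    path = outdir / "ssr_table.tsv"
                    ssr_mod.write_ssr_table(ssr_hits, path)
                    outs = [path]
                elif step == 9:
                    if config.archive_format == "none" or not result_files:
                        record(step, "skipped", "nothing to archive"
                               if config.archive_format != "none"
                               else "archiving disabled")
                        continue
                    path = outdir / "results.zip"
                    package_results(result_files, path)
                    outs = [path]
                else:
                    outs = []
            except Exception as exc:
                record(step, "failed", str(exc))
                note("aborting after step failure")
                return summary
            result_files.extend(outs)
            record(step, "done", outputs=outs)
        note("run finished")
    return summary


def _scan_ssrs(config: RunConfig, contigs, summary: RunSummary):
    hits = ssr_mod.scan_contigs(
        contigs, config.ssr_min_unit, config.ssr_max_unit,
        config.ssr_min_score,
    )
    summary.counts["ssrs"] = len(hits)
    return hits


def _load_contigs(config: RunConfig) -> list[aio.QualSequence]:
    if config.contigs_fastq is not None:
        return aio.read_fastq(config.contigs_fastq)
    return aio.read_fasta_qual(config.contigs_fasta, config.contigs_qual)


def _step_clean(config, outdir, summary, note):
    if config.raw_reads_fastq is None:
        note("step 2: no raw_reads_fastq configured; nothing to clean")
        return []
    raw = aio.read_fastq(config.raw_reads_fastq)
    kept, discarded = filter_reads(
        raw, config.min_read_len, config.min_mean_quality
    )
    summary.counts.update(
        reads_in=len(raw), reads_kept=len(kept),
        discarded_short=discarded["short"],
        discarded_low_quality=discarded["low_quality"],
    )
    path = outdir / "cleaned_reads.fastq"
    aio.write_fastq(kept, path)
    return [path]


def _step_call(config, outdir, contigs, columns_by_contig):
    all_columns = [
        col for c in contigs for col in columns_by_contig[c.id]
    ]
    calls = call_snps(all_columns, config.detection)
    by_id = {c.id: c for c in contigs}
    tcs = [
        aio.tcs_from_pileup(col, by_id[col.contig_id])
        for col in all_columns
        if col.depth_R + col.gap_count > 0
    ]
    tcs.sort(key=lambda r: (r.contig_id, r.position))
    tcs_path = outdir / "assembly.tcs"
    aio.write_tcs(tcs, tcs_path)
    snp_contigs = aio.annotate_fasta_titles(contigs, calls)
    fasta_path = outdir / "snp_contigs.fasta"
    with open(fasta_path, "w") as fh:
        for s in snp_contigs:
            title = f"{s.id} {s.description}".rstrip()
            fh.write(f">{title}\n{s.bases}\n")
    return calls, [tcs_path, fasta_path]


def _step_characterize(config, outdir, contigs, reads, calls, ssr_hits):
    annotations, no_orf = place_snps(
        calls, contigs, min_len=config.orf_min_len, mode=config.orf_mode
    )
    orf_path = outdir / "snp_orfs.fasta"
    write_orf_fasta(annotations, orf_path)
    metrics = compute_metrics(contigs, reads or [], calls, ssr_hits)
    snp_report = outdir / "snp_report.html"
    render_snp_report(calls, annotations, metrics, snp_report)
    metrics_report = outdir / "metrics.html"
    render_metrics_report(metrics, metrics_report)
    log.info(
        "characterized %d SNPs (%d placed in ORFs, %d without ORF)",
        len(calls), len(annotations), len(no_orf),
    )
    return annotations, [orf_path, snp_report, metrics_report]
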