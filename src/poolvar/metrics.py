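"""Assembly metrics, HTML reports and result packaging.

N50 follows the cumulative-sum definition: the length of the shortest
contig in the minimal set of longest contigs whose summed length reaches
half of the assembly total.  GC% is computed over contig consensus bases
excluding N.  Reports are single-file dependency-free HTML, with the SNP
table kept free of nested markup so rows paste cleanly into spreadsheets.
The archive step writes a standard zip with sorted member paths and fixed
timestamps, so identical inputs yield a byte-identical archive.
"""

from __future__ import annotations

import html
import statistics
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from poolvar.errors import PoolvarError

_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)


@dataclass
class AssemblyMetrics:
    n_contigs: int
    n_reads: int
    total_bases: int
    min_len: int
    mean_len: float
    median_len: float
    max_len: int
    n50: int
    gc_pct: float
    mean_depth: float
    snp_count: int
    ssr_count: int


def n50(lengths: Sequence[int]) -> int:
    """Shortest length in the minimal set of longest contigs covering half
    the total bases."""
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise PoolvarError("empty length set")


def compute_metrics(contigs, reads, calls, ssrs) -> AssemblyMetrics:
    """Derive all dataset metrics from the in-memory run state."""
    if not contigs:
        raise PoolvarError("nothing to report: empty contig set")
    lengths = [len(c) for c in contigs]
    total = sum(lengths)
    gc = sum(c.bases.count("G") + c.bases.count("C") for c in contigs)
    acgt = total - sum(c.bases.count("N") for c in contigs)
    aligned = sum(
        sum(1 for b in r.aligned_bases if b != "-") for r in reads
    )
    return AssemblyMetrics(
        n_contigs=len(contigs),
        n_reads=len(reads),
        total_bases=total,
        min_len=min(lengths),
        mean_len=total / len(lengths),
        median_len=statistics.median(lengths),
        max_len=max(lengths),
        n50=n50(lengths),
        gc_pct=100.0 * gc / acgt if acgt else 0.0,
        mean_depth=aligned / total if total else 0.0,
        snp_count=len(calls),
        ssr_count=len(ssrs),
    )


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 0.3em 0.8em; text-align: left; }}
th {{ background: #eee; }}
</style></head>
<body>
<h1>{title}</h1>
{body}
</body></html>
"""


def _table(headers: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    head = "".join(f"<th>{html.escape(h)}</th>" for h in headers)
    lines = [f"<table>\n<tr>{head}</tr>"]
    for row in rows:
        cells = "".join(f"<td>{html.escape(str(v))}</td>" for v in row)
        lines.append(f"<tr>{cells}</tr>")
    lines.append("</table>")
    return "\n".join(lines)


def render_snp_report(calls, annotations, metrics: AssemblyMetrics, sink) -> None:
    """One table row per accepted SNP, with its ORF context when placed."""
    by_call = {(a.call.contig_id, a.call.position): a for a in annotations}
    headers = [
        "Contig", "Position", "SNP", "Major count", "Minor count",
        "Major mean Q", "Minor mean Q", "Depth", "ORF frame",
        "Left flank", "Right flank",
    ]
    rows = []
    for c in calls:
        ann = by_call.get((c.contig_id, c.position))
        rows.append([
            c.contig_id,
            c.position + 1,
            f"SNP:{c.position + 1}:{c.major_base}/{c.minor_base}",
            c.count_major,
            c.count_minor,
            f"{c.mean_qual_major:.1f}",
            f"{c.mean_qual_minor:.1f}",
            c.depth,
            f"{ann.frame:+d}" if ann else "no ORF",
            ann.left_flank if ann else "",
            ann.right_flank if ann else "",
        ])
    body = (
        f"<p>{metrics.snp_count} putative SNP(s) across "
        f"{metrics.n_contigs} contig(s).</p>\n" + _table(headers, rows)
    )
    _write(sink, _PAGE.format(title="Putative SNP report", body=body))


def render_metrics_report(metrics: AssemblyMetrics, sink) -> None:
    """The dataset-metrics page of the run."""
    rows = [
        ("Contigs", metrics.n_contigs),
        ("Reads", metrics.n_reads),
        ("Total assembled bases", metrics.total_bases),
        ("Shortest contig (bp)", metrics.min_len),
        ("Mean contig length (bp)", f"{metrics.mean_len:.1f}"),
        ("Median contig length (bp)", f"{metrics.median_len:.1f}"),
        ("Longest contig (bp)", metrics.max_len),
        ("N50 (bp)", metrics.n50),
        ("GC content (%)", f"{metrics.gc_pct:.2f}"),
        ("Mean read depth", f"{metrics.mean_depth:.2f}"),
        ("Putative SNPs", metrics.snp_count),
        ("Putative SSRs", metrics.ssr_count),
    ]
    body = _table(["Metric", "Value"], rows)
    _write(sink, _PAGE.format(title="Assembly metrics", body=body))


def _write(sink, text: str) -> None:
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def package_results(paths: Sequence, archive_sink) -> None:
    """Zip every result file under a flat results/ prefix, deterministically.

    Member order is sorted by archive name and every timestamp is fixed, so
    re-running on identical inputs reproduces the archive byte for byte.
    """
    if not paths:
        raise PoolvarError("no result files to package")
    missing = [str(p) for p in paths if not Path(p).is_file()]
    if missing:
        raise PoolvarError(f"missing result files: {', '.join(missing)}")
    members = sorted((f"results/{Path(p).name}", Path(p)) for p in paths)
    with zipfile.ZipFile(archive_sink, "w", zipfile.ZIP_DEFLATED) as zf:
        for arcname, path in members:
            info = zipfile.ZipInfo(arcname, date_time=_ZIP_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, path.read_bytes())
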