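"""Run configuration: an INI-like key=value file with self-documented keys.

Sections and keys (all optional unless noted):

    [inputs]
    contigs_fasta  = assembly consensus FASTA            (this + contigs_qual,
    contigs_qual   = paired FASTA.QUAL                    or contigs_fastq)
    contigs_fastq  = assembly consensus as FASTQ (Phred+33)
    reads_sam      = read-to-contig alignments, SAM      (steps 4-5)
    raw_reads_fastq = raw reads for the cleaning step    (step 2)

    [snp]
    min_coverage  = minimum column depth C               (default 15)
    min_variants  = minimum V2 count, absolute ("4") or
                    percent of C ("20%")                 (default 20%)
    min_quality   = minimum per-variant mean quality     (default 70)

    [orf]
    orf_min_len = minimum ORF length in bases            (default 90)
    orf_mode    = stop-to-stop | atg-to-stop             (default stop-to-stop)

    [ssr]
    ssr_min_unit  = smallest repeat unit                 (default 1)
    ssr_max_unit  = largest repeat unit                  (default 6)
    ssr_min_score = minimum tract score                  (default 12)

    [filter]
    min_read_len     = minimum kept read length          (default 50)
    min_mean_quality = minimum kept read mean quality    (default 20)

    [run]
    output_dir     = run directory                       (default pipeline_out)
    steps          = comma list of enabled steps 1-9     (default 2,4,5,6,8,9)
    archive_format = zip | none                          (default zip)

Unknown keys warn; missing keys take the documented defaults; a
type-invalid value raises a :class:`ConfigError` naming the key.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

from poolvar.caller import DetectionConfig
from poolvar.errors import ConfigError
from poolvar import orfs, ssr

log = logging.getLogger("poolvar")

_KNOWN_KEYS = {
    "inputs": {"contigs_fasta", "contigs_qual", "contigs_fastq",
               "reads_sam", "raw_reads_fastq"},
    "snp": {"min_coverage", "min_variants", "min_quality"},
    "orf": {"orf_min_len", "orf_mode"},
    "ssr": {"ssr_min_unit", "ssr_max_unit", "ssr_min_score"},
    "filter": {"min_read_len", "min_mean_quality"},
    "run": {"output_dir", "steps", "archive_format"},
}

DEFAULT_STEPS = frozenset({2, 4, 5, 6, 8, 9})


@dataclass
class RunConfig:
    contigs_fasta: Path | None = None
    contigs_qual: Path | None = None
    contigs_fastq: Path | None = None
    reads_sam: Path | None = None
    raw_reads_fastq: Path | None = None
    output_dir: Path = Path("pipeline_out")
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    orf_min_len: int = orfs.DEFAULT_MIN_ORF_LEN
    orf_mode: str = "stop-to-stop"
    ssr_min_unit: int = ssr.DEFAULT_MIN_UNIT
    ssr_max_unit: int = ssr.DEFAULT_MAX_UNIT
    ssr_min_score: int = ssr.DEFAULT_MIN_SCORE
    min_read_len: int = 50
    min_mean_quality: float = 20.0
    steps_enabled: frozenset[int] = DEFAULT_STEPS
    archive_format: str = "zip"

    def validate(self) -> None:
        if self.contigs_fastq is None and not (
            self.contigs_fasta and self.contigs_qual
        ):
            raise ConfigError(
                "inputs need contigs_fasta + contigs_qual, or contigs_fastq"
            )
        for key in ("contigs_fasta", "contigs_qual", "contigs_fastq",
                    "reads_sam", "raw_reads_fastq"):
            path = getattr(self, key)
            if path is not None and not Path(path).is_file():
                raise ConfigError(f"{key}: file not found: {path}")
        if self.steps_enabled & {4, 5} and self.reads_sam is None:
            raise ConfigError("steps 4-5 enabled but reads_sam is not set")
        if not self.steps_enabled <= set(range(1, 10)):
            raise ConfigError("steps must be within 1..9")
        if self.orf_mode not in orfs.ORF_MODES:
            raise ConfigError(f"orf_mode: unknown mode {self.orf_mode!r}")
        if self.archive_format not in {"zip", "none"}:
            raise ConfigError(f"archive_format must be zip or none")


def _get(parser, section, key, cast, default, path=None):
    if not parser.has_option(section, key):
        return default
    raw = parser.get(section, key)
    try:
        return cast(raw)
    except (ValueError, TypeError) as exc:
        where = f" in {path}" if path else ""
        raise ConfigError(
            f"[{section}] {key}: invalid value {raw!r}{where}"
        ) from exc


def _parse_min_variants(raw: str) -> tuple[int | None, float | None]:
    raw = raw.strip()
    if raw.endswith("%"):
        frac = float(raw[:-1]) / 100.0
        return None, frac
    return int(raw), None


def _parse_steps(raw: str) -> frozenset[int]:
    return frozenset(int(tok) for tok in raw.replace(" ", "").split(",") if tok)


def parse_config(source) -> RunConfig:
    """Parse a run-configuration file into a validated RunConfig."""
    parser = configparser.ConfigParser(
        inline_comment_prefixes=("#", ";"), interpolation=None
    )
    path = str(source)
    try:
        read = parser.read(path)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not read:
        raise ConfigError(f"cannot read config file {path}")

    for section in parser.sections():
        if section not in _KNOWN_KEYS:
            log.warning("config: unknown section [%s] ignored", section)
            continue
        for key in parser.options(section):
            if key not in _KNOWN_KEYS[section]:
                log.warning("config: unknown key [%s] %s ignored", section, key)

    def get(section, key, cast, default):
        return _get(parser, section, key, cast, default, path)

    def get_path(section, key):
        return get(section, key, Path, None)

    mv_abs, mv_frac = None, DetectionConfig().min_variants_frac
    if parser.has_option("snp", "min_variants"):
        try:
            mv_abs, mv_frac = _parse_min_variants(parser.get("snp", "min_variants"))
        except ValueError as exc:
            raise ConfigError(
                f"[snp] min_variants: invalid value "
                f"{parser.get('snp', 'min_variants')!r} in {path}"
            ) from exc

    try:
        detection = DetectionConfig(
            min_coverage=get("snp", "min_coverage", int,
                             DetectionConfig().min_coverage),
            min_variants=mv_abs,
            min_variants_frac=mv_frac,
            min_quality=get("snp", "min_quality", float,
                            DetectionConfig().min_quality),
        )
    except ConfigError as exc:
        raise ConfigError(f"[snp] section: {exc}") from exc

    cfg = RunConfig(
        contigs_fasta=get_path("inputs", "contigs_fasta"),
        contigs_qual=get_path("inputs", "contigs_qual"),
        contigs_fastq=get_path("inputs", "contigs_fastq"),
        reads_sam=get_path("inputs", "reads_sam"),
        raw_reads_fastq=get_path("inputs", "raw_reads_fastq"),
        output_dir=get("run", "output_dir", Path, RunConfig.output_dir),
        detection=detection,
        orf_min_len=get("orf", "orf_min_len", int, orfs.DEFAULT_MIN_ORF_LEN),
        orf_mode=get("orf", "orf_mode", str, "stop-to-stop"),
        ssr_min_unit=get("ssr", "ssr_min_unit", int, ssr.DEFAULT_MIN_UNIT),
        ssr_max_unit=get("ssr", "ssr_max_unit", int, ssr.DEFAULT_MAX_UNIT),
        ssr_min_score=get("ssr", "ssr_min_score", int, ssr.DEFAULT_MIN_SCORE),
        min_read_len=get("filter", "min_read_len", int, 50),
        min_mean_quality=get("filter", "min_mean_quality", float, 20.0),
        steps_enabled=get("run", "steps", _parse_steps, DEFAULT_STEPS),
        archive_format=get("run", "archive_format", str, "zip"),
    )
    cfg.validate()
    return cfg
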