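# Methods

## Model and procedure

poolvar treats a de-novo assembly of a pooled panel as a stack of
independent pileup columns. Reads are projected onto contig coordinates
from their SAM alignments (CIGAR operators M/=/X become column bases, D/N
become gaps, I and S consume read bases without creating columns, H and P
consume nothing; soft-clipped bases are excluded because they are not
assembly evidence). Each column tallies base counts and quality lists per
base. Coordinates are 0-based half-open internally; every serialized
position is 1-based.

A column is called a putative SNP when, for its two most frequent base
variants V1 and V2,

    R ≥ C,   count(V2) ≥ v_min,   meanQ(V1) ≥ Q_min,   meanQ(V2) ≥ Q_min,

where R counts only reads contributing a real base (A/C/G/T). The model
assumes the pool is deep enough that a true minor allele recurs in several
independent reads, while sequencing errors are rare and low-quality; the
count threshold filters singleton noise and the quality threshold filters
systematic miscalls. There is no statistical model of allele frequency and
no significance value — the criterion is a deterministic filter, which is
what makes its behaviour easy to audit for array-design use.

## Parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `min_coverage` (C) | 15 | reads | minimum column depth R |
| `min_variants` (v_min) | 20 % of C | reads | minimum V2 count; a percent value is resolved as ⌈frac·C⌉ so rounding never weakens it; an absolute integer passes through |
| `min_quality` (Q_min) | 70 | input quality scale | minimum mean quality of each of V1 and V2 |
| `orf_min_len` | 90 | bases | minimum ORF length (30 codons) |
| `orf_mode` | stop-to-stop | — | stop-free stretches; `atg-to-stop` available |
| `ssr_min_unit`/`ssr_max_unit` | 1 / 6 | bases | repeat unit range |
| `ssr_min_score` | 12 | bases | minimum tract score (≥ 6 perfect dinucleotide units) |
| `min_read_len` / `min_mean_quality` (filter) | 50 / 20 | bases / quality | read-cleaning thresholds |

Q_min is interpreted on whatever scale the input qualities use. The default
of 70 exceeds raw Phred maxima and matches assembler-adjusted consensus
scales; no rescaling is performed, so users of raw Phred+33 data must lower
it. Quality means are exact (unrounded) internally and rounded half-up only
in the TCS serialization.

## Design choices where the design was open

- **Variant ranking ties.** Equally frequent variants are ordered by higher
  mean quality, then fixed base order A<C<G<T. Determinism everywhere was
  preferred over any data-driven tie-break.
- **Tri-allelic columns.** The criterion is evaluated on the top two
  variants only; a third variant never blocks or creates a call. Extra
  variants remain visible in the TCS.
- **Gaps and Ns.** Both are tallied per column but excluded from R, since
  the criterion reasons about base variants; including them would inflate
  coverage toward calls. TCS total coverage counts bases + gaps (reads
  spanning the column with an opinion), still excluding N.
- **ORF convention.** Stop-to-stop by default because EST contigs are often
  5'-truncated, so requiring ATG would discard real coding context. The
  best ORF for a SNP is the longest containing it, ties broken by the more
  centered SNP, then frame order +1..+3, −1..−3. The SNP's major allele is
  substituted before scanning so the reported ORF carries the consensus
  variant; on reverse frames the reported sequence and offset follow the
  reading direction.
- **SSR regions.** A hit is a maximal exactly-periodic tract: it ends where
  the period-k self-match breaks. Substitutions therefore split a repeat
  into separate tracts instead of diluting one; every reported tract has
  identity 100 % and score equal to its span. The score is defined as
  matches − mismatches against the tiled per-phase-majority consensus, and
  is what cross-unit overlap reduction compares (ties: smaller unit, then
  leftmost). Indels within a tract are out of scope.
- **TCS dialect.** Tab-separated with a commented header (contig, 1-based
  position, consensus, coverage, five counts, four mean qualities); defined
  by this package and symmetric under read/write.
- **Archive.** Standard zip with sorted member names and fixed timestamps:
  a transport convenience that keeps runs byte-reproducible.
- **External stages.** Raw-data extraction, assembly, contaminant
  screening, protein-database search and gene-ontology annotation are
  adapter steps that are logged and skipped; the core pipeline is fully
  functional from FASTA/QUAL + SAM inputs, which keeps it hermetic and
  testable.
- **Read filter double-failures.** A read that is both short and low
  quality is tallied once, as short (length is checked first).

## The synthetic-data generator

`poolvar.fixtures` emulates the target setting: contigs drawn uniformly
over ACGT; reads of fixed length (default 400 bases, medium-read scale)
tiling each contig to a target depth at uniformly random starts; planted
biallelic sites at which each covering read independently carries the minor
allele with probability `minor_fraction` (the pooled allele frequency);
optional per-base substitution errors; constant or two-level quality
models. Planted sites are kept at least a read length away from contig
ends so they see full depth. A second generator produces a two-haplotype
pool (haplotypes differing at Bernoulli-divergence sites, reads pooled
without origin labels), mimicking a merged pair of strain datasets.

What it does **not** emulate: homopolymer-length errors characteristic of
pyrosequencing, flowgram noise, coverage biases, chimeric reads, or
assembly errors (reads are generated already aligned, standing in for the
external assembler). Passing tests therefore demonstrate the correctness
of the column arithmetic, the criterion, and the annotations under the
stated sampling model — not robustness to real 454 artefacts.

Because allele sampling is binomial, a planted site's minor count at depth
30 and fraction 0.3 occasionally falls below v_min = 3; the recovery tests
pin their generator seeds, and all stochastic tests state their seeds
explicitly.

## Numerical and degenerate-input conventions

- Fractional v_min uses ceiling; resolved v_min < 1 is a configuration
  error.
- Empty columns and monomorphic columns are valid inputs that never call.
- Zero-depth columns are materialized in the pileup (one column per contig
  position) but omitted from the TCS.
- N50 is the length of the shortest contig in the minimal set of longest
  contigs covering half the total bases; it is always the length of some
  contig. GC % excludes N bases. An empty contig set is an error.
- Reads without base qualities are rejected at SAM parsing; a gap column
  contributes no quality.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
the standard panel is 20 contigs × 2 kb at depth 30 with 50 planted SNPs
(~1.2 M aligned bases), the criterion cross-check uses 10,000 randomized
columns, the ORF cross-check 1,000 random 300–900 base sequences, and the
SSR recovery 100 × 1 kb sequences. These sizes exercise every code path
while keeping a full run in seconds.

## Known limitations

- Indel variation is not called; read insertions relative to the contig
  are discarded by design.
- Paired-end semantics, BAM/CRAM, and MAF input are unsupported (SAM text
  only).
- The criterion has no error model: at shallow depth or high error rates
  its false-negative/false-positive balance is governed entirely by the
  three thresholds.
- One archive format (zip) and single-end reads only.
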