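# poolvar

Reference-free SNP discovery in pooled de-novo assemblies.

## The problem

Population studies of non-model organisms often start from a sequencing
library that pools many individuals without barcodes: there is no reference
genome to map against and no way to tell which read came from which
individual. Finding reliable SNPs in such data — typically medium-read
transcriptome (EST) assemblies — means deciding, column by column of a
de-novo assembly, whether the second-most-frequent base is genuine
population variation or sequencing noise. The SNPs that survive are the
raw material for designing genotyping arrays.

poolvar takes an existing assembly (contig consensus sequences with per-base
qualities, plus read-to-contig alignments in SAM), mines it for high-confidence
SNPs, characterizes each SNP's open-reading-frame context, scans for
microsatellites (SSRs), and renders spreadsheet-friendly HTML reports.

## The detection criterion

For each assembly column, let V1 and V2 be the most and second-most
frequent base variants, R the number of reads contributing a base to the
column, and Q̄ the mean base quality of a variant. The column is a putative
SNP iff

```
ΣR ≥ C   ∧   ΣV2 ≥ v_min   ∧   Q̄_V1 ≥ Q_min   ∧   Q̄_V2 ≥ Q_min
```

with defaults C = 15, v_min = 20 % of C (rounded up, so 3 at the default
coverage), and Q_min = 70 on the input's own quality scale. All three are
configurable. Deletions and N bases never count toward R.

## Worked example

Generate a synthetic pooled-panel assembly with known planted variation,
then run the pipeline on it:

```
$ poolvar fixtures --outdir demo --seed 42 --n-contigs 5 --contig-len 2000 \
      --depth 30 --n-snps 10 --n-ssrs 1
fixture written to demo (10 planted SNPs, 5 planted SSRs)

$ poolvar run --config demo/pipeline.rc
step 1 (extract): skipped — disabled in configuration
step 2 (clean): skipped — disabled in configuration
step 3 (assemble): skipped — disabled in configuration
step 4 (pileup): done
step 5 (snp-call): done
step 6 (characterize): done
step 7 (ontology): skipped — disabled in configuration
step 8 (ssr-scan): done
step 9 (package): done
reads: 750
snps: 10
ssrs: 12
outputs in demo/out
```

All 10 planted SNPs are recovered (`snps: 10`) with no false positives;
the 12 SSR hits are the 5 planted tracts plus incidental short repeats in
the random background that clear the default score of 12. The run
directory contains:

- `assembly.tcs` — per-column tally: consensus base, coverage, A/C/G/T/gap
  counts and per-base mean qualities;
- `snp_contigs.fasta` — contigs carrying SNPs, with title tokens such as
  `SNP:162:A/T` (1-based position, major/minor allele);
- `snp_orfs.fasta` — each SNP's best ORF, e.g.
  `>contig001_ORF1 frame:+1 SNP:162:A/T`;
- `ssr_table.tsv` — e.g. `contig001  907  939  ACCT  4  8  33  100.0`,
  an (ACCT)×8 tract with score 33 (span length) and identity 100 %;
- `snp_report.html`, `metrics.html` — the SNP table and dataset metrics
  (N50, GC %, depth, counts);
- `results.zip` — all of the above, packaged deterministically.

The same machinery is available as a library (`poolvar.build_pileup`,
`poolvar.call_snps`, `poolvar.find_orfs`, `poolvar.find_ssrs`, ...), and
`--skip`/`--only` select pipeline steps, mirroring the 9-step layout above.

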