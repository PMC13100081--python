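# neorank

Neoepitope discovery and prioritization engine for tumor–normal multi-omics.
From filtered somatic variants, expressed gene fusions, per-base coverage
tracks and expression tables, `neorank` produces:

- a **ranked, component-scored table of candidate MHC class I neoepitopes**
  (8–11-mer peptides from missense SNVs, in-frame/frameshift indels, and
  fusion junctions),
- a **callable-territory tumor mutational burden (TMB)** report with Ti/Tv and
  breadth-of-coverage,
- a **DNA–RNA concordance** report separating functional amplifications from
  capture artifacts and transcription-only elevation.

The priority score is a bounded product on 0–100:

```
priority = 100 · L(%Rank) · tanh(expr/scale) · clonality · foreignness
```

with `L(x) = 1/(1 + e^{5(x−2)})` (inflection at 2% rank), a TPM ≥ 1 expression
gate (FFPM for fusions), VAF as the clonality weight (fusions treated as
clonal), a wild-type-counterpart-based foreignness/agretopicity component, and
hard zeroing of exact self-matches against the reference proteome.

Real peptide–MHC %Rank values come from an external predictor via
`neorank.binding.import_predictions` (NetMHCpan-style tabular output); a
deterministic digest-based stub predictor is bundled so the whole engine runs
and is tested with no licensed tools.

## CLI

```sh
# generate a fully synthetic, seeded toy cohort with ground truth
neorank simulate --seed 1 --out-dir cohort/

# run every stage end-to-end
neorank run --manifest cohort/manifest.yaml --out-dir out/
```

`out/` then contains `tmb.tsv`, `candidates.tsv` (fixed 18-column schema,
deterministic row order), `concordance.tsv`, `counts.tsv` and `run.log`.
Individual stages are available as `tmb`, `peptides`, `fusions`, `bind`,
`score`, and `concordance` subcommands; thresholds are configurable through a
YAML config passed to `run --config` (defaults: 10× depth, TPM ≥ 1, 0.5/2.0
strong/weak rank cutoffs, ≥ 5 fusion support reads).

Input formats: VCF 4.x with a companion tab-separated effect table (or
embedded VEP-style CSQ), Arriba-dialect fusion TSV, Kallisto-dialect
abundance TSV, samtools-depth-style depth TSV, BED (0-based half-open),
FASTA, and a one-allele-per-line HLA list.

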