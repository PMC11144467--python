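# mrtarget

Drug-target Mendelian randomization (MR) from two-sample GWAS summary
statistics, with no external data dependencies: every pipeline stage can be
exercised against a built-in synthetic summary-statistics generator with
known ground truth.

## What it does

- **`mrtarget.summary_data`** — typed containers for GWAS summary statistics
  (`VariantRecord`, `SummaryDataset`, `GeneRegion`), TSV I/O with
  configurable column maps (GWAS-SSF-like names by default), and allele
  harmonization of exposure/outcome pairs (allele swaps, strand flips,
  conservative dropping of ambiguous palindromic variants).
- **`mrtarget.instrument_selection`** — greedy LD pruning of
  genome-wide-significant variants (ascending p-value, keep iff r² with all
  kept variants is below threshold), optional cis-region restriction, and
  instrument-strength diagnostics: per-variant `F = (beta/se)²`,
  `r² = F/(n−2+F)`, combined `F = ((n−k−1)/k)·R²/(1−R²)`, with a weak-
  instrument flag at combined F < 10.
- **`mrtarget.mr_estimators`** — Wald ratio, inverse-variance-weighted
  (fixed or multiplicative-random-effects) primary estimator, MR-Egger
  regression (intercept = directional-pleiotropy test, t with k−2 df),
  bootstrap weighted median, and odds-ratio reporting per unit *lower*
  exposure.
- **`mrtarget.colocalization`** — per-variant approximate Bayes factors and
  enumeration of the five causal configurations (H0–H4) in log space.
- **`mrtarget.synthetic_data`** — summary-level simulation of paired
  exposure (quantitative) and outcome (rare binary) GWAS with configurable
  causal effect, explained variance, pleiotropy mode, and block LD; plus a
  regional simulator with planted colocalization configurations.
- **`mrtarget.pipeline`** — multi-exposure × multi-outcome orchestration
  with per-exposure Benjamini–Hochberg FDR control, sensitivity analyses
  (skipped with an explicit reason when fewer than 3 instruments are
  available), and TSV/JSON reports including a forest-plot-ready table.

## CLI

```sh
# generate a synthetic study with known truth
mrtarget simulate --seed 1 --k-variants 100 --theta 0.2 --outdir sim/

# select uncorrelated significant instruments (optionally cis)
mrtarget select --exposure sim/exposure.tsv --ld sim/ld.tsv \
    --p-threshold 5e-8 --r2-threshold 0.1 \
    --region 1:55505221-55530525 --flank 10000 --out instruments.tsv

# harmonize and estimate
mrtarget harmonize --exposure instruments.tsv --outcome sim/outcome.tsv --out h.tsv
mrtarget estimate --harmonized h.tsv --out-prefix mr

# regional colocalization
mrtarget coloc --trait1 region_exp.tsv --trait2 region_out.tsv --out coloc.json

# full grid from a YAML config
mrtarget run --config analysis.yaml --outdir results/
```

A minimal `analysis.yaml`:

```yaml
exposures:
  - name: ldl_via_target
    path: sim/exposure.tsv
    region: "1:55505221-55530525"
    flank: 10000
    p_threshold: 5.0e-8
    r2_threshold: 0.1
outcomes:
  - name: outcome_a
    path: sim/outcome.tsv
ld_path: sim/ld.tsv
fdr_alpha: 0.05
report_lowering: true
```

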