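# mitranet

A tested, reusable pipeline from small-RNA differential expression through
signed miRNA-target network scoring to target selection and qPCR/phenotype
validation, exercised end-to-end on synthetic data with known ground truth.

## What it does

- **`mitranet.synthetic_data`** — generates every pipeline input with planted
  truth: negative-binomial miRNA count matrices with planted fold changes,
  three-dialect interaction tables (a validated catalog plus two score-based
  prediction sources) with brute-force-computable true node strengths, Ct
  tables with planted group shifts, and per-animal echocardiography tables
  with a three-arm study structure (sham / compensated hypertrophy /
  decompensated failure).
- **`mitranet.phenotyping`** — biplane-ellipsoid LV volumes, stroke volume,
  cardiac output, ejection fraction, cube-law LV mass, organ-weight ratios,
  and study-arm assignment by the terminal EF < 30% rule.
- **`mitranet.diffexpr`** — CPM normalization, per-miRNA two-sample tests
  with normality-driven test choice, and the dual gate p < 0.05 AND fold
  change > 1.5 (or < 1/1.5), both strict. Also a free-text signed-list
  parser with species-prefix expansion.
- **`mitranet.target_network`** — reads the three interaction dialects with
  strict score thresholds (prediction score > 80.0; repression score
  < −1.2), builds the signed bipartite network (+1 edges from upregulated,
  −1 from downregulated miRNAs, one edge per miRNA-gene pair), computes
  per-gene node strengths (positive strength predicts target
  downregulation), selects targets in three tiers, and exports
  SIF/GraphML/edge-list TSV.
- **`mitranet.validation`** — 2^−ΔCT relative expression, reference-group
  normalization, per-gene group comparison, and concordance scoring of
  predicted versus observed regulation.
- **`mitranet.stats`** — shared test selection: KS (Lilliefors) normality →
  t-test / Mann-Whitney for two groups, ANOVA+Tukey / Kruskal-Wallis+Dunn
  for three or more.
- **`mitranet.cli`** — stage subcommands plus a YAML-driven `run-all` that
  writes a checksummed run manifest.

## CLI

```sh
mitranet simulate --outdir data --seed 1
mitranet phenotype --echo data/echo.tsv --out pheno.tsv --groups-out arms.tsv
mitranet de --counts data/counts.tsv --groups data/groups.tsv \
    --group-a AB_LVH --group-b AB_HF --out de.tsv --signed-out signed.tsv
mitranet network --signed-set signed.tsv --validated data/validated.tsv \
    --mirdb data/mirdb.tsv --mirsvr data/mirsvr.tsv \
    --edges-out edges.tsv --strengths-out strengths.tsv
mitranet select --strengths strengths.tsv --unidirectional-strength 6 \
    --n-random-strong 4 --seed 1 --out selected.tsv
mitranet qpcr --ct-table data/qpcr.tsv --reference-group AB_LVH \
    --test-group AB_HF --rel-out rel.tsv --comparisons-out comp.tsv
mitranet concordance --strengths strengths.tsv --comparisons comp.tsv \
    --out concordance.tsv
mitranet run-all --config pipeline.yaml      # or: --outdir out --seed 1
mitranet summarize --outdir out --json
```

`run-all` executes simulate → phenotype → de → network → select → validate →
concordance; stages can be toggled via the `stages` list in the YAML config,
and every threshold (`alpha`, `fc_threshold`, `mirdb_min`, `mirsvr_max`,
`ef_cutoff`) is a config key.

## Layout

```
src/mitranet/       package modules
tests/              pytest suite (tests/test_acceptance.py holds the
                    acceptance criteria)
scripts/acceptance.py
```
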