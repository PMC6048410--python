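# immunoscape

Immune-landscape scoring and sidedness analysis for bulk tumor expression
cohorts. The package chains:

1. **data_io** — validated readers/writers for expression matrices
   (TSV / MatrixMarket), GMT gene sets and clinical tables (with an
   anatomic-site → left/right side mapping; rectum counts as left).
2. **ssgsea** — a from-scratch single-sample gene set enrichment engine
   (rank-weighted running sum, `alpha = 0.25` default, deterministic
   lexicographic tie handling, optional global max−min normalization).
3. **scores** — composite immune scores per sample: cytolytic activity
   (geometric mean of PRF1/GZMA), T-cell infiltration score (mean of nine
   z-scored T-subset enrichments), CD8/Treg ratio (min–max rescaled to
   [0.01, 1] first), pathway/APM/IFN readouts, overall infiltration.
4. **phenotype** — High/Median/Low infiltration tiers via Ward hierarchical
   clustering (Euclidean or 1−Pearson distance on z-scored rows, k = 3),
   median splits (Hi strictly above the median) and crossed Hi/Lo classes.
5. **stats** — Mann–Whitney / Welch t / one-way ANOVA contrasts,
   Pearson/Spearman correlations, chi-square / Fisher contingency tests.
6. **survival** — Kaplan–Meier, k-stratum log-rank and univariate Cox
   (Newton with Efron tie handling), implemented directly; KM plots use a
   0–4,000-day display window (a plot default, not a data filter).
7. **simulate** — a synthetic cohort generator with planted ground truth
   (infiltration tiers, side shifts, right-side-only negative VEGFA–CD8
   coupling, score-linked exponential survival) so every stage is
   recovery-testable offline.
8. **pipeline / cli** — end-to-end orchestration from one YAML config with
   deterministic JSON summaries.

## CLI

```sh
immunoscape simulate --seed 1 --n-samples 200 --out cohort/
immunoscape ssgsea --expr cohort/expression.tsv --gmt cohort/sets.gmt \
    --alpha 0.25 --out cohort/enrichment.tsv
immunoscape score --expr cohort/expression.tsv --gmt cohort/sets.gmt \
    --enrichment cohort/enrichment.tsv --out cohort/scores.tsv
immunoscape classify --enrichment cohort/enrichment.tsv \
    --scores cohort/scores.tsv --split cyt --out cohort/classes.tsv
immunoscape compare --scores cohort/scores.tsv --clinical cohort/clinical.tsv \
    --score cyt --score tis --out cohort/stats.tsv
immunoscape survive --clinical cohort/clinical.tsv --classes cohort/classes.tsv \
    --label cyt_split --plot cohort/km.png
immunoscape run-all --config examples/fixture.yaml --outdir run/
```

`run-all` writes `expression.tsv`, `sets.gmt`, `clinical.tsv`,
`enrichment.tsv`, `scores.tsv`, `classes.tsv`, `stats.tsv`, KM plots and a
deterministic `summary.json` (byte-identical across reruns for a fixed
config and seed).

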