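# necrosig

Derive, score and evaluate directional gene-expression signatures in
two-group cohorts. The pipeline covers:

- **I/O & preprocessing** (`necrosig.io`): tab-separated expression matrices,
  clinical CSV with a controlled vocabulary, GMT gene sets with `_UP`/`_DN`
  directional pairing, MAF mutation tables; log2 transform, max-probe
  collapse, rule-based cohort filtering.
- **Differential expression** (`necrosig.diffexp`): two-class moderated
  t-statistic `d = Δmean / (s + s0)` with permutation-estimated FDR
  (percent scale), signed linear fold changes, and threshold-based signature
  derivation (defaults: |FC| ≥ 2.5, q < 0.008%).
- **Signature scoring** (`necrosig.signatures`): directional sum-score
  (Σ UP − Σ DOWN per sample), zero/mean/quartile grouping schemes,
  z-normalized signature panels, Jaccard overlap, complete-linkage
  Euclidean clustering of score tables.
- **Association statistics** (`necrosig.associations`): cross-tabulations
  with within-column percentages, uncorrected Pearson chi-square,
  Mann–Whitney U, Kruskal–Wallis H, Spearman rank correlation, multivariate
  logistic regression.
- **Survival** (`necrosig.survival`): disease-specific endpoint preparation,
  Kaplan–Meier product-limit estimates, k-group log-rank test, Cox
  proportional hazards by Newton–Raphson with Efron (default) or Breslow
  tie handling and Wald 95% CIs.
- **Mutation contrast** (`necrosig.mutations`): per-sample burden, per-gene
  mutated-sample frequencies by group, Fisher exact tests with
  Benjamini–Hochberg adjustment, pathway-level aggregation.
- **Synthetic cohorts** (`necrosig.simulate`): planted UP/DOWN genes on the
  log2 scale, score-proportional hazards with calibrated censoring,
  group-dependent mutation rates, subtype label mixing, plus recovery
  metrics (sensitivity / precision / direction accuracy) against the truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed-table
contingency arithmetic, signature/Cox recovery on synthetic cohorts,
type-I-error calibration of log-rank and chi-square, and dual-route oracle
equivalences (pooled-t, hypergeometric enumeration, 1 − ECDF).

## CLI

```sh
# make a synthetic cohort
necrosig simulate --out cohort/ --seed 7 --n-pos 50 --n-neg 50 --n-genes 1000

# end-to-end: derive -> score -> associate -> survive -> mutate
necrosig run --expression cohort/expression.tsv --clinical cohort/clinical.csv \
    --maf cohort/mutations.maf --out run/ --seed 7 \
    --permutations 500 --fc-min 2.5 --q-max 0.008 --grouping zero --ties efron
```

Each stage is also a subcommand (`derive`, `score`, `associate`, `survive`,
`mutate`) and a plain library call. A YAML config can replace the flags
(`necrosig run --config run.yaml`); any flag overrides its config key. Every
run writes tidy CSV/TSV outputs and a `manifest.json` with input/output
hashes, the seed, and per-stage timings — identical config + seed reproduces
identical outputs.

Panel signatures and pathway memberships ship as editable GMT files under
`src/necrosig/resources/` (placeholder gene lists; replace with curated
sets for real analyses).

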