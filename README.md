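# occubiome

Compositional microbiome analysis and random-forest occupation
classification for shotgun-metagenomic feature tables.

Forensic and epidemiological studies increasingly ask what a saliva or
stool sample reveals about its donor. This package implements the
downstream analysis stack for one such question — can the oral/gut
microbiome distinguish students from manual laborers? — starting from
annotated count tables (species, KEGG pathways, resistance genes, …)
rather than raw reads. It is aimed at bioinformaticians who have count
tables and per-sample metadata and want the full pipeline: compositional
preprocessing, diversity testing, ordination, differential abundance,
and a sparse classifier, plus a synthetic-study generator so every stage
is testable without any sequencing data.

## What it computes

- **Preprocessing** — removal of undetermined annotations, closure to
  relative abundances, prevalence filtering, taxonomic aggregation
  (`occubiome.tables`).
- **α diversity** — Shannon index H = −Σ pᵢ log₂ pᵢ per sample, with a
  gated two-group test: Shapiro–Wilk and Levene decide between Student's
  t and the Wilcoxon rank-sum test; Bonferroni across the cohort
  contrasts (`occubiome.alpha`).
- **β diversity** — Hellinger distance HD = √Σ(√aᵢ−√bᵢ)², principal
  coordinates analysis, and ANOSIM (Clarke's R over distance ranks) with
  seeded permutation p-values, exact on small instances
  (`occubiome.beta`).
- **Differential abundance** — per-feature gated tests with Bonferroni
  correction, median-of-pairwise-differences summaries with
  distribution-free CIs, and a two-class LDA effect-size screen flagging
  features with |log₁₀ score| > 4 (`occubiome.diffabund`).
- **Classifier** — Bayesian-multiplicative zero replacement, recursive
  feature elimination ranked by mean-decrease-accuracy averaged over 100
  random forests per step, and best-model selection (fewest features at
  the highest train/test accuracy) (`occubiome.classifier`).
- **Synthetic studies** — a Dirichlet-multinomial generator with
  structural zeros, planted group-informative features and lifestyle
  covariates, plus ground-truth recovery scoring (`occubiome.simulate`).

## Worked example

The `analysis/` scripts run the whole pipeline on a synthetic study of
20 male students vs 20 male laborers (200 species, 5 informative at
8-fold change):

```sh
python analysis/01_simulate_study.py
python analysis/02_cohort_and_alpha.py
python analysis/03_beta_ordination.py
python analysis/04_differential_abundance.py
python analysis/05_occupation_classifier.py
```

which prints (abridged):

```
[saliva] mean Shannon: laborer=5.333, student=5.620
  MLa vs MSt                     wilcoxon adj p=4.799e-05 *
  male smokers vs non-smokers    wilcoxon adj p=0.2398
  male drinkers vs non-drinkers  t-test   adj p=0.8609
[saliva] ANOSIM occupation  R=+0.2642  p=0.001
[saliva] ANOSIM smoking     R=+0.0226  p=0.247
[saliva] 3 features significant after Bonferroni (1/5 planted); LDA screen flags 2 (2/5 planted)
[saliva] all 178 features: train 100.00% / test 91.67%; best model 12 features: train 100.00% / test 100.00%
[feces]  all 180 features: train 100.00% / test 83.33%; best model 2 features: train 100.00% / test 100.00%
```

Reading this: occupation shifts both Shannon diversity (adjusted
p ≈ 5·10⁻⁵) and community composition (ANOSIM R = 0.26, p = 0.001),
while smoking and drinking do not separate the groups; the recursive
elimination then finds a small feature subset whose forest ensemble
classifies both the 28 training and the 12 held-out samples perfectly.
Stage tables (Shannon indices, distance matrices, PCoA coordinates,
per-feature tests, elimination traces, serialized models) land under
`results/`.

The same pipeline is scriptable on any TSV count table + metadata via
the CLI: `occubiome simulate | summarize | diversity | ordinate |
anosim | diffabund | lefse | train | predict | run-all` (see
`occubiome --help`).

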