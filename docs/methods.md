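# Methods

`occubiome` implements the downstream half of a shotgun-metagenomics
occupation study: starting from annotated feature-count tables (taxa at a
chosen rank, or functional features such as KEGG pathways), it asks
whether two occupation groups — students and manual laborers — carry
distinguishable oral/gut microbial communities, and builds a classifier
that predicts occupation from a handful of features.

## Data model and preprocessing

A `FeatureTable` is a features × samples matrix of non-negative integer
read counts, optionally carrying a seven-rank lineage (kingdom …
species) per feature. Preprocessing follows the standard compositional
workflow:

- **Undetermined removal.** Features whose id or lineage matches
  "unassigned" or "uncultured" (case-insensitive substrings,
  configurable) are dropped before anything else.
- **Relative abundance.** Each sample is closed to proportions over the
  determined features; a zero-total sample is an error naming the
  sample. All downstream diversity statistics operate on these
  compositions.
- **Prevalence filter.** Features detected (count > 0) in fewer than a
  threshold number of samples are removed before model construction.
  The threshold is a parameter (default 10) rather than a constant
  because reasonable analyses use anything from 25% of samples upward;
  detection means presence, with no minimum count.
- **Taxonomic aggregation** sums species counts to any higher rank and
  conserves per-sample totals exactly (integer arithmetic).

## Alpha diversity

Shannon diversity of a composition p is H = −Σᵢ pᵢ log₂ pᵢ (zero entries
contribute nothing; H ranges from 0 for a single feature to log₂ m for
the uniform composition). Group comparisons use a gated test choice:
Shapiro–Wilk normality per group and Levene homogeneity of variance
(mean-centred by default, median-centred by flag) at `gate_alpha = 0.05`;
Student's t-test only when all three gates pass, otherwise the Wilcoxon
rank-sum test (scipy's `mannwhitneyu`, exact when tie-free and small,
normal approximation with continuity correction otherwise; mid-ranks for
ties). Constant groups force the Wilcoxon path with a logged note, since
Shapiro–Wilk is undefined there. Five standard cohort contrasts are run
per sample type (laborers vs male students, female vs male students,
laborers vs female students, male smokers vs non-smokers, male drinkers
vs non-drinkers); contrasts with fewer than three samples in a group are
skipped with a warning, and Bonferroni correction is applied within each
family of conducted contrasts.

## Beta diversity, PCoA, ANOSIM

The Hellinger distance between compositions a and b is
HD = √Σᵢ(√aᵢ − √bᵢ)², the Euclidean distance of square-root-transformed
compositions, bounded by √2 for disjoint supports. A `halved` flag
switches to the √(Σ/2) convention bounded by 1; the two differ by a
constant factor, so every rank-based conclusion (ANOSIM) and all PCoA
geometry are unaffected by the choice — the tests assert this rather
than assuming it.

PCoA is classical metric scaling: Gower double-centering B = −½·J D² J,
eigendecomposition, coordinates scaled by √λ for positive eigenvalues.
Negative eigenvalues are reported but their axes dropped; no
Lingoes/Cailliez correction is applied because Hellinger matrices are
Euclidean-embeddable (asserted in the tests). The implementation is
cross-checked against scikit-bio's independently written `pcoa`.

ANOSIM uses Clarke's statistic R = (r̄_between − r̄_within)/(n(n−1)/4)
over mid-ranked pairwise distances, R ∈ [−1, 1]. The p-value is the
add-one permutation estimator (1 + #{R_perm ≥ R_obs})/(1 + B) with
seeded label permutations (default B = 999), so p is never zero; on
two-group instances with at most 20,000 distinct assignments the exact
enumeration (including the observed labelling) is used instead. R is
cross-checked against scikit-bio, the exact p against brute-force
enumeration.

## Differential abundance

Per-feature testing reuses the gated test choice per feature, with the
Bonferroni family equal to the number of features tested. The
pairwise-difference summary forms all n₁·n₂ between-group differences of
one feature (400 for 20 + 20 samples), reporting their median with a
distribution-free CI that takes the l-th smallest/largest difference,
l chosen from Binomial(N, ½) order-statistic coverage. The interval
treats the N dependent differences as a pooled sample — a deliberate
simplification; bootstrap or normal-approximation intervals would be
alternatives.

The LDA effect-size screen (two-class only): samples are rescaled to a
constant sum of 10⁶ (making results invariant to closure or depth), a
Kruskal–Wallis test at α = 0.05 screens features, and each surviving
feature's effect is estimated over 30 bootstrap subsamples (two-thirds
of each class without replacement): a linear discriminant axis is fitted
(unit-norm; falling back to the standardized mean-difference direction
when the within-class scatter is singular), and the per-feature effect
is the mean of the between-class difference along that axis and the raw
between-class mean difference. The score is log₁₀(1 + mean effect), and
a feature is flagged iff it passed the screen and the score exceeds the
threshold (default 4 — i.e. an effect of ~10⁴ in the 10⁶-scaled units).
Multi-class and subclass structure are out of scope.

## Zero replacement and the occupation classifier

Count zeros are replaced by their posterior Dirichlet expectation
(Bayesian-multiplicative treatment): for a sample with total n and m
features, a zero becomes qᵢ·s/(n+s) and the non-zero proportions are
multiplicatively shrunk so the sample still sums to one, preserving
their ratios exactly. Priors: SQ (default; uniform base qᵢ = 1/m,
strength s = √n, chosen for its closed form), Bayes–Laplace (uniform
base, s = m), and GBM (base proportional to each feature's geometric
mean observed proportion across samples, s = √n — this package's
definition of the geometric variant).

Model construction per sample type: female students are excluded (no
female laborers exist to balance them), the prevalence filter and BM
treatment are applied, and the data are split into stratified train/test
sets (default 28/12, largest-remainder rounding per class, seeded).
Recursive feature elimination then runs from all m features down to one.
Each step grows `n_forests` (default 100) random forests of
`trees_per_forest` (default 500) sklearn decision trees with mtry = ⌊√m⌋
and unlimited depth, each tree on its own bootstrap; per-feature
importance is mean decrease accuracy — the drop in out-of-bag accuracy
when the feature's column is permuted — averaged over the forests.
Averaging per-forest MDA over forests equals averaging over all member
trees, so all trees of a step are grown in one pass and grouped into
forests only for voting. For speed, permuted feature columns are drawn
as three distinct permutation blocks per step, cycled across trees,
rather than one fresh permutation per tree; with ≥200 trees per step the
residual shared-permutation noise is far below the between-feature
importance differences. The lowest-importance feature is eliminated
(ties: lexicographically last id). Ensemble accuracy is a nested
majority vote — each forest votes the majority of its trees, a tied
forest contributes half a vote to each class, and the ensemble takes the
majority over forests; the mean single-forest accuracy is also computed.
The best model is the step with lexicographically maximal
(test accuracy, train accuracy), preferring the fewest features among
equals, and is refitted with that step's recorded seed so its accuracies
reproduce exactly. Models serialize to a JSON manifest (features,
classes, seeds, accuracies, preprocessing provenance) plus a pickled
tree payload.

## The synthetic-study generator

Real data for this design are two groups of ~20 samples over hundreds to
thousands of sparse compositional features. The generator emulates
exactly that: a base composition from a symmetric Dirichlet
(concentration 0.3 → uneven, dominance-heavy profiles), 5 informative
features planted among the above-median-abundance half (so the signal
sits in detectable taxa) with balanced directions (alternating
enrichment toward each group, as differential taxa in real cohorts go
both ways) and a multiplicative fold-change (default 8×) in the laborer
group, structural zeros dropping each feature from each sample with
probability 0.3, per-sample depths from a negative binomial (mean 10⁵,
dispersion 5; `inf` gives fixed depth), and multinomial counts at the
drawn depth, so column sums equal depths exactly. Covariates
(smoking/drinking/gender) are drawn independently of counts at per-group
rates mirroring a male student/laborer cohort. Everything is
reproducible from one seed.

What the generator does not emulate: taxon–taxon correlation, batch or
compositional covariate effects, group-dependent presence/absence (real
discriminative taxa are often present in one group and absent in the
other; here absence is class-independent and only abundance differs),
and library-size confounding. Passing recovery tests therefore show that
the pipeline finds multiplicative abundance signals in sparse
compositions — not that it handles every structure of real data.

## Benchmark problem sizes and numerical choices

The planted-feature recovery benchmark runs 20 + 20 samples, 200
features, 5 informative at 8×, stratified 28/12 split, 100 forests per
elimination step with 2 trees per forest — a deliberate desk-scale
reduction of the default 500; the ensemble behind each step still has
200 trees. The benchmark fixes sequencing depth: BM imputation maps all
zeros of a sample to the same depth-dependent value, so with variable
depths a forest can memorize training zeros sample-by-sample, which
rewards degenerate one/two-feature models and confounds the question the
benchmark asks. Null-calibration checks run 250 replicates at 10 + 10
samples and 80 features (the calibration of rank tests and permutation
p-values does not depend on these sizes) and 199 ANOSIM permutations.

A known limitation, demonstrated by the recovery benchmark itself: with
28 training samples and ~200 features, backward elimination keeps a few
noise features that separate the training classes by chance, and the
minimum-feature best-model rule often settles on 2–3 features once they
reach perfect accuracy on the small test set. The selected model's
accuracy is therefore a much more stable quantity than the identity of
its features — feature sets selected at this sample size should be read
as candidates, not as the underlying informative set.

Other numerics: compositions are validated to sum to 1 within 1e-9; BM
output rows sum to 1 within 1e-12 with non-zero ratios preserved to
1e-12; PCoA treats eigenvalues below max(1e-12, 1e-10·λ₁) as null;
ANOSIM permutation comparisons use a 1e-12 tolerance on R; importance
ties use a 1e-15 band. Degenerate inputs (constant groups, all-zero
samples, classes lost in a bootstrap) either take documented fallbacks
or raise errors naming the offending sample/feature.
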