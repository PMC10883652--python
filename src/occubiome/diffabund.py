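"""Per-feature differential abundance, pairwise-difference summaries and a
two-class LDA effect-size (LEfSe-style) screen.

Per-feature testing reuses the gate-selected t-test/Wilcoxon machinery
with a Bonferroni family equal to the number of features tested.  The
pairwise-difference summary forms all n1*n2 between-group differences of
a feature's relative abundance and reports their median with a
distribution-free, order-statistic confidence interval.  The LEfSe-style
screen rescales samples to a constant sum of 1e6, keeps features passing
a Kruskal-Wallis test, estimates a linear-discriminant effect size over
bootstrap subsamples and flags features whose log10 score exceeds a
threshold (default 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .alpha import GATE_ALPHA, two_sample_test
from .tables import CompositionTable


@dataclass(frozen=True)
class FeatureTestResult:
    feature_id: str
    test: str
    statistic: float
    raw_p: float
    adjusted_p: float
    group_means: tuple[float, float]
    group_medians: tuple[float, float]


def _two_group_arrays(
    composition: CompositionTable, group_labels
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, str]]:
    labels = np.asarray(group_labels)
    if len(labels) != len(composition.sample_ids):
        raise ValueError("group_labels length must match the number of samples")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    arr = composition.values.to_numpy(dtype=float)
    return arr, labels == uniq[0], labels == uniq[1], (str(uniq[0]), str(uniq[1]))


def per_feature_tests(
    composition: CompositionTable, group_labels, gate_alpha: float = GATE_ALPHA
) -> list[FeatureTestResult]:
    """Gate-selected two-group test of every feature's relative abundance,
    Bonferroni-corrected over all features tested."""
    arr, in1, in2, _ = _two_group_arrays(composition, group_labels)
    if in1.sum() < 3 or in2.sum() < 3:
        raise ValueError("each group needs >= 3 samples")
    m = arr.shape[0]
    results = []
    for i, fid in enumerate(composition.feature_ids):
        x, y = arr[i, in1], arr[i, in2]
        choice, stat, p = two_sample_test(x, y, gate_alpha)
        results.append(
            FeatureTestResult(
                feature_id=fid,
                test=choice.test,
                statistic=stat,
                raw_p=p,
                adjusted_p=min(1.0, p * m),
                group_means=(float(x.mean()), float(y.mean())),
                group_medians=(float(np.median(x)), float(np.median(y))),
            )
        )
    return results


def feature_test_frame(results: list[FeatureTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "raw_p": [r.raw_p for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
        }
    ).set_index("feature_id")


@dataclass(frozen=True)
class MedianDiffCI:
    n1: int
    n2: int
    n_differences: int
    median: float
    lower: float
    upper: float
    confidence: float


def pairwise_difference_summary(x, y, confidence: float = 0.95) -> MedianDiffCI:
    """Median of all n1*n2 pairwise differences x_i - y_j with a
    distribution-free CI from the order statistics of the differences.

    The interval takes the l-th smallest and l-th largest difference,
    where l is the largest integer with Binom(N, 1/2) lower-tail mass at
    l-1 not exceeding (1-confidence)/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    n = diffs.size
    tail = (1.0 - confidence) / 2.0
    lo_rank = int(stats.binom.ppf(tail, n, 0.5))  # largest l-1 with cdf <= tail
    if stats.binom.cdf(lo_rank, n, 0.5) > tail:
        lo_rank -= 1
    l = max(1, lo_rank + 1)
    return MedianDiffCI(
        n1=len(x),
        n2=len(y),
        n_differences=int(n),
        median=float(np.median(diffs)),
        lower=float(diffs[l - 1]),
        upper=float(diffs[n - l]),
        confidence=confidence,
    )


@dataclass(frozen=True)
class LefseFeature:
    feature_id: str
    screen_p: float
    score: float            # log10(1 + mean LDA effect); nan if screened out
    enriched_group: str
    passed: bool


SCALE = 1e6  # per-sample total after rescaling, the customary LEfSe unit


def lefse_two_class(
    composition: CompositionTable | pd.DataFrame,
    group_labels,
    alpha: float = GATE_ALPHA,
    lda_threshold: float = 4.0,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> list[LefseFeature]:
    """Two-class LDA effect-size screen of differentially abundant features.

    A feature is flagged iff its Kruskal-Wallis screening p is below
    ``alpha`` and its log10 LDA score exceeds ``lda_threshold``.  The LDA
    effect of a surviving feature is, per bootstrap subsample, the mean
    of (i) the absolute between-class difference of the feature's
    component along the (unit-norm) discriminant axis and (ii) its raw
    between-class mean difference, both in the 1e6-rescaled units.

    Accepts either a CompositionTable or any non-negative features x
    samples frame; every sample is rescaled to total ``1e6``, so results
    are invariant to per-sample closure or depth.
    """
    if isinstance(composition, pd.DataFrame):
        totals = composition.sum(axis=0)
        if (totals <= 0).any() or (composition.to_numpy() < 0).any():
            raise ValueError("abundance frame must be non-negative with positive totals")
        composition = CompositionTable(composition / totals, feature_kind="unspecified")
    arr, in1, in2, (g1, g2) = _two_group_arrays(composition, group_labels)
    if in1.sum() < 3 or in2.sum() < 3:
        raise ValueError("each class needs >= 3 samples")
    X = arr.T * SCALE  # samples x features, each row sums to SCALE
    y = np.where(in1, 0, 1)

    screen_p = np.array(
        [
            stats.kruskal(X[in1, i], X[in2, i]).pvalue
            if np.ptp(X[:, i]) > 0
            else 1.0
            for i in range(X.shape[1])
        ]
    )
    surviving = np.flatnonzero(screen_p < alpha)
    scores = np.full(X.shape[1], np.nan)

    if surviving.size:
        rng = np.random.default_rng(seed)
        Xs = X[:, surviving]
        idx1, idx2 = np.flatnonzero(in1), np.flatnonzero(in2)
        k1 = max(2, int(round(boot_fraction * idx1.size)))
        k2 = max(2, int(round(boot_fraction * idx2.size)))
        effects = np.zeros(surviving.size)
        for _ in range(n_boot):
            sub = np.concatenate(
                [rng.choice(idx1, k1, replace=False), rng.choice(idx2, k2, replace=False)]
            )
            Xb, yb = Xs[sub], y[sub]
            raw = np.abs(Xb[yb == 0].mean(axis=0) - Xb[yb == 1].mean(axis=0))
            w = _lda_axis(Xb, yb)
            proj = Xb * w  # per-feature component along the discriminant axis
            aligned = np.abs(proj[yb == 0].mean(axis=0) - proj[yb == 1].mean(axis=0))
            effects += (aligned + raw) / 2.0
        scores[surviving] = np.log10(1.0 + effects / n_boot)

    mean1, mean2 = X[in1].mean(axis=0), X[in2].mean(axis=0)
    results = []
    for i, fid in enumerate(composition.feature_ids):
        results.append(
            LefseFeature(
                feature_id=fid,
                screen_p=float(screen_p[i]),
                score=float(scores[i]),
                enriched_group=g1 if mean1[i] >= mean2[i] else g2,
                passed=bool(screen_p[i] < alpha and scores[i] > lda_threshold),
            )
        )
    return results


def _lda_axis(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Unit-norm discriminant direction; falls back to the standardized
    mean-difference direction when the within-class scatter is singular."""
    try:
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(Xb, yb)
        w = lda.scalings_[:, 0]
    except Exception:
        diff = Xb[yb == 0].mean(axis=0) - Xb[yb == 1].mean(axis=0)
        sd = Xb.std(axis=0)
        w = diff / np.where(sd > 0, sd, 1.0)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lefse_frame(results: list[LefseFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "screen_p": [r.screen_p for r in results],
            "score": [r.score for r in results],
            "enriched_group": [r.enriched_group for r in results],
            "passed": [r.passed for r in results],
        }
    ).set_index("feature_id")
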