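"""Shannon diversity and the normality/variance-gated two-group comparison.

The two-sample test is chosen per comparison: Shapiro-Wilk normality in
each group and Levene homogeneity of variance across groups; only when
all three gates pass at ``gate_alpha`` is Student's t-test used,
otherwise the Wilcoxon rank-sum (Mann-Whitney) test.  Five standard
cohort comparisons are run per sample type (laborers vs male students,
female vs male students, laborers vs female students, male smokers vs
non-smokers, male drinkers vs non-drinkers), Bonferroni-corrected as one
family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CompositionTable

log = logging.getLogger(__name__)

GATE_ALPHA = 0.05


class CompositionError(ValueError):
    """Raised when a vector is not a valid composition."""


def _check_composition(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise CompositionError("composition has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise CompositionError(f"composition sums to {p.sum()!r}, not 1")
    return p


def shannon_index(composition_vector) -> float:
    """Shannon diversity H = -sum p_i log2 p_i of one sample's composition.

    Zero abundances contribute nothing (0 log 0 := 0).  H is 0 for a
    single-feature sample and log2(m) for the uniform composition.
    """
    p = _check_composition(composition_vector)
    return float(stats.entropy(p, base=2))


def shannon_per_sample(composition: CompositionTable) -> pd.Series:
    """Shannon index of every sample in a composition table."""
    arr = composition.values.to_numpy(dtype=float)
    return pd.Series(
        stats.entropy(arr, base=2, axis=0), index=composition.sample_ids, name="shannon"
    )


@dataclass(frozen=True)
class TestChoice:
    """Which two-sample test the gates selected, and why."""

    test: str                      # "t-test" or "wilcoxon"
    shapiro_p: tuple[float, float]
    levene_p: float
    alpha: float
    note: str = ""


@dataclass(frozen=True)
class GroupComparisonResult:
    comparison: str
    sample_type: str
    groups: tuple[str, str]
    n: tuple[int, int]
    choice: TestChoice
    statistic: float
    raw_p: float
    adjusted_p: float
    group_means: tuple[float, float]
    group_medians: tuple[float, float]


def choose_two_sample_test(
    x, y, gate_alpha: float = GATE_ALPHA, levene_center: str = "mean"
) -> TestChoice:
    """Select t-test vs Wilcoxon via Shapiro-Wilk and Levene gates.

    Constant vectors leave Shapiro-Wilk undefined; the choice then falls
    back to Wilcoxon with an explanatory note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both groups need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        note = "constant group; Shapiro-Wilk undefined, forcing Wilcoxon"
        log.info(note)
        return TestChoice("wilcoxon", (math.nan, math.nan), math.nan, gate_alpha, note)
    sp_x = stats.shapiro(x).pvalue
    sp_y = stats.shapiro(y).pvalue
    lv = stats.levene(x, y, center=levene_center).pvalue
    normal = sp_x > gate_alpha and sp_y > gate_alpha
    test = "t-test" if normal and lv > gate_alpha else "wilcoxon"
    return TestChoice(test, (float(sp_x), float(sp_y)), float(lv), gate_alpha)


def two_sample_test(
    x, y, gate_alpha: float = GATE_ALPHA, levene_center: str = "mean"
) -> tuple[TestChoice, float, float]:
    """Run the gate-selected test; returns (choice, statistic, p-value)."""
    choice = choose_two_sample_test(x, y, gate_alpha, levene_center)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if choice.test == "t-test":
        res = stats.ttest_ind(x, y, equal_var=True)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return choice, float(res.statistic), float(res.pvalue)


#: the five standard cohort comparisons: (label, filter for group 1, group 2)
STANDARD_COMPARISONS = (
    ("MLa vs MSt", {"occupation": "laborer", "gender": "M"}, {"occupation": "student", "gender": "M"}),
    ("FSt vs MSt", {"occupation": "student", "gender": "F"}, {"occupation": "student", "gender": "M"}),
    ("MLa vs FSt", {"occupation": "laborer", "gender": "M"}, {"occupation": "student", "gender": "F"}),
    ("male smokers vs non-smokers", {"gender": "M", "smoking": "yes"}, {"gender": "M", "smoking": "no"}),
    ("male drinkers vs non-drinkers", {"gender": "M", "drinking": "yes"}, {"gender": "M", "drinking": "no"}),
)


def _subset(metadata: pd.DataFrame, flt: dict[str, str]) -> pd.Index:
    mask = pd.Series(True, index=metadata.index)
    for col, val in flt.items():
        mask &= metadata[col] == val
    return metadata.index[mask]


def compare_alpha_across_groups(
    composition: CompositionTable,
    metadata: pd.DataFrame,
    gate_alpha: float = GATE_ALPHA,
    comparisons=STANDARD_COMPARISONS,
    family_size: int | None = None,
) -> list[GroupComparisonResult]:
    """Shannon-index comparisons across the standard cohort contrasts.

    One Bonferroni family per call (default: the comparisons actually
    conducted).  Comparisons with fewer than three samples in either
    group are skipped with a warning.
    """
    shannon = shannon_per_sample(composition)
    metadata = metadata.loc[shannon.index]
    sample_types = metadata["sample_type"].unique()
    results: list[GroupComparisonResult] = []
    raw: list[tuple] = []
    for stype in sample_types:
        meta_t = metadata[metadata["sample_type"] == stype]
        for label, f1, f2 in comparisons:
            g1, g2 = _subset(meta_t, f1), _subset(meta_t, f2)
            if len(g1) < 3 or len(g2) < 3:
                log.warning(
                    "skipping %r (%s): group sizes %d and %d", label, stype, len(g1), len(g2)
                )
                continue
            x, y = shannon[g1].to_numpy(), shannon[g2].to_numpy()
            choice, stat, p = two_sample_test(x, y, gate_alpha)
            raw.append((label, stype, g1, g2, x, y, choice, stat, p))
    k = family_size if family_size is not None else len(raw)
    for label, stype, g1, g2, x, y, choice, stat, p in raw:
        results.append(
            GroupComparisonResult(
                comparison=label,
                sample_type=stype,
                groups=tuple(label.split(" vs ", 1)),
                n=(len(x), len(y)),
                choice=choice,
                statistic=stat,
                raw_p=p,
                adjusted_p=min(1.0, p * k),
                group_means=(float(np.mean(x)), float(np.mean(y))),
                group_medians=(float(np.median(x)), float(np.median(y))),
            )
        )
    return results


def comparison_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Tidy results table (one row per comparison)."""
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "sample_type": [r.sample_type for r in results],
            "test": [r.choice.test for r in results],
            "statistic": [r.statistic for r in results],
            "raw_p": [r.raw_p for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
        }
    )
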