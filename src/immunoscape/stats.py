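"""Group comparisons, correlations and contingency tests for cohort contrasts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss

from .data_io import ValidationError


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    group_sizes: tuple[int, ...]
    statistic: float
    p_value: float
    direction: int  # sign of the location difference (first minus second group)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str = "pearson"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")


def _two_groups(values: pd.Series, labels: pd.Series) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    values, labels = values.align(labels, join="inner")
    uniq = sorted(pd.unique(labels))  # deterministic group order => stable direction
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq}")
    a = values[labels == uniq[0]].to_numpy(dtype=float)
    b = values[labels == uniq[1]].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    return a, b, (str(uniq[0]), str(uniq[1]))


def compare_groups(
    values: pd.Series, labels: pd.Series, test: str = "mann_whitney"
) -> ComparisonResult:
    """Two-group comparison: two-sided Mann-Whitney or Welch t-test.

    Mann-Whitney uses the exact null when both groups have n <= 20 and the
    pooled values are tie-free, and the normal approximation with continuity
    correction otherwise.
    """
    a, b, _ = _two_groups(values, labels)
    direction = int(np.sign(a.mean() - b.mean()))
    if test == "mann_whitney":
        pooled = np.concatenate([a, b])
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(a) <= 20 and len(b) <= 20 and tie_free) else "asymptotic"
        res = ss.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
        return ComparisonResult("mann_whitney", (len(a), len(b)), float(res.statistic), float(res.pvalue), direction)
    if test == "t_test":
        if len(a) < 2 or len(b) < 2:
            raise ValidationError("t-test needs >= 2 observations per group")
        res = ss.ttest_ind(a, b, equal_var=False)
        return ComparisonResult("t_test_welch", (len(a), len(b)), float(res.statistic), float(res.pvalue), direction)
    raise ValueError(f"unknown test {test!r}")


def anova_oneway(values: pd.Series, labels: pd.Series) -> ComparisonResult:
    """One-way ANOVA across k >= 2 groups (F with k-1, n-k df)."""
    values, labels = values.align(labels, join="inner")
    groups = [values[labels == g].to_numpy(dtype=float) for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    sizes = tuple(len(g) for g in groups)
    if any(s < 2 for s in sizes):
        raise ValidationError(f"every group needs >= 2 observations, got sizes {sizes}")
    f, p = ss.f_oneway(*groups)
    if np.isnan(f):  # all groups constant and equal
        f, p = 0.0, 1.0
    means = [g.mean() for g in groups]
    direction = int(np.sign(means[0] - means[-1]))
    return ComparisonResult("anova_oneway", sizes, float(f), float(p), direction)


def correlate(x: pd.Series, y: pd.Series, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided t-transform p (n-2 df)."""
    x, y = x.align(y, join="inner")
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    if len(xv) < 3:
        raise ValidationError("correlation needs n >= 3")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValidationError("correlation inputs must be finite")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValidationError("zero variance in x or y; correlation undefined")
    if method == "pearson":
        r, p = ss.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = ss.spearmanr(xv, yv)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return CorrelationResult(float(r), float(p), len(xv), method)


def contingency_test(table: np.ndarray | pd.DataFrame) -> ComparisonResult:
    """Chi-square independence test; Fisher exact for 2x2 with small expecteds.

    The switch to Fisher happens when any expected count falls below 5.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2 x 2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError("contingency table must hold non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if arr.shape == (2, 2) and (expected < 5).any():
        odds, p = ss.fisher_exact(arr.astype(int), alternative="two-sided")
        return ComparisonResult(
            "fisher_exact", tuple(int(s) for s in arr.sum(axis=1)), float(odds), float(p), 0
        )
    stat, p, _, _ = ss.chi2_contingency(arr, correction=False)
    return ComparisonResult(
        "chi_square", tuple(int(s) for s in arr.sum(axis=1)), float(stat), float(p), 0
    )


def infiltration_side_ratio(
    enrich_scores: pd.DataFrame, side: pd.Series, delta: float = 0.01
) -> pd.Series:
    """Per cell type, ratio of side-wise mean min-max-rescaled scores (left/right).

    Values above 1 mean more infiltration on the left.  This axis is an
    interpretation of a qualitative display, not a published formula.
    """
    side = side.loc[[s for s in enrich_scores.columns if s in side.index]]
    left = side.index[side == "left"]
    right = side.index[side == "right"]
    if len(left) == 0 or len(right) == 0:
        raise ValidationError("both sides must be represented")
    lo = enrich_scores.min(axis=1)
    rng = (enrich_scores.max(axis=1) - lo).replace(0, np.nan)
    rescaled = (
        enrich_scores.sub(lo, axis=0).div(rng, axis=0) * (1 - delta) + delta
    )
    out = rescaled[left].mean(axis=1) / rescaled[right].mean(axis=1)
    out.name = "left_right_ratio"
    return out


def comparisons_to_frame(results: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Long-format table: one row per contrast."""
    rows = []
    for key, res in results.items():
        rows.append(
            {
                "contrast": key,
                "test": res.test_name,
                "group_sizes": "/".join(str(s) for s in res.group_sizes),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows).set_index("contrast")
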