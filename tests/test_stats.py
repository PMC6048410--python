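import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from immunoscape.data_io import ValidationError
from immunoscape.stats import (
    anova_oneway,
    compare_groups,
    contingency_test,
    correlate,
    infiltration_side_ratio,
)


def _series(vals, prefix="s"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))], dtype=float)


def _labels(labels):
    return pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])


def mw_exact_enumeration(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = np.delete(pooled, list(idx_a))
        u = sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
        return u

    u_obs = u_stat(range(n1))
    mu = n1 * (len(pooled) - n1) / 2.0
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    extreme = sum(abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us)
    return extreme / len(us)


class TestCompareGroups:
    def test_mw_exact_small(self):
        values = _series([1, 2, 3, 4])
        labels = _labels(["a", "a", "b", "b"])
        res = compare_groups(values, labels, "mann_whitney")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.direction == -1

    def test_mw_exact_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.permutation(20)[:4].astype(float)
            b = (rng.permutation(20)[:5] + 30).astype(float)
            b = b + rng.random(5)  # keep values distinct from a
            values = pd.Series(
                np.concatenate([a, b]), index=[f"s{i}" for i in range(9)]
            )
            labels = _labels(["a"] * 4 + ["b"] * 5)
            res = compare_groups(values, labels, "mann_whitney")
            assert res.p_value == pytest.approx(
                mw_exact_enumeration(a, b), abs=1e-12
            )

    def test_identical_groups_null(self):
        values = _series([1, 2, 3, 1, 2, 3])
        labels = _labels(["a"] * 3 + ["b"] * 3)
        mw = compare_groups(values, labels, "mann_whitney")
        assert mw.p_value == pytest.approx(1.0)
        tt = compare_groups(values, labels, "t_test")
        assert tt.statistic == pytest.approx(0.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1.0, 100)
        b = rng.normal(0.0, 1.0, 100)
        values = pd.Series(np.concatenate([a, b]),
                           index=[f"s{i}" for i in range(200)])
        labels = _labels(["hi"] * 100 + ["lo"] * 100)
        for test in ("mann_whitney", "t_test"):
            res = compare_groups(values, labels, test)
            assert res.p_value < 0.01
            assert res.direction == 1

    def test_empty_group_error(self):
        values = _series([1, 2, 3])
        labels = _labels(["a", "a", "a"])
        with pytest.raises(ValidationError):
            compare_groups(values, labels)

    def test_three_groups_rejected(self):
        values = _series([1, 2, 3])
        labels = _labels(["a", "b", "c"])
        with pytest.raises(ValidationError, match="2 groups"):
            compare_groups(values, labels)


class TestAnova:
    def test_identical_groups_null(self):
        values = _series([1, 2, 1, 2, 1, 2])
        labels = _labels(["a", "a", "b", "b", "c", "c"])
        res = anova_oneway(values, labels)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_anova_table(self):
        # groups (1,2), (1,2), (101,102): SSB/2 over SSW/3
        values = _series([1, 2, 1, 2, 101, 102])
        labels = _labels(["a", "a", "b", "b", "c", "c"])
        res = anova_oneway(values, labels)
        grand = values.mean()
        ssb = sum(
            2 * (values[labels == g].mean() - grand) ** 2 for g in ("a", "b", "c")
        )
        ssw = sum(
            ((values[labels == g] - values[labels == g].mean()) ** 2).sum()
            for g in ("a", "b", "c")
        )
        f_hand = (ssb / 2) / (ssw / 3)
        assert res.statistic == pytest.approx(f_hand)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        values = _series(rng.normal(size=30))
        labels = _labels(list("abc") * 10)
        res1 = anova_oneway(values, labels)
        perm = rng.permutation(values.index)
        res2 = anova_oneway(values.loc[perm], labels.loc[perm])
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_singleton_group_rejected(self):
        values = _series([1, 2, 3, 4, 5])
        labels = _labels(["a", "a", "b", "b", "c"])
        with pytest.raises(ValidationError):
            anova_oneway(values, labels)


class TestCorrelate:
    def test_perfect_linearity(self):
        x = _series([1, 2, 3, 4, 5])
        assert correlate(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = _series([1, 2, 3, 4, 5])
        assert correlate(x, -x).r == pytest.approx(-1.0)

    def test_spearman_hand_value(self):
        # ranks d = (1, 1, 1, 1, 0); rho = 1 - 6*4 / (5*24) = 0.8
        x = _series([1, 2, 3, 4, 5])
        y = _series([2, 1, 4, 3, 5])
        res = correlate(x, y, method="spearman")
        assert res.r == pytest.approx(0.8)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x = _series(rng.normal(size=20))
        y = _series(rng.normal(size=20))
        assert correlate(x, y).r == pytest.approx(correlate(y, x).r)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = _series(rng.normal(size=20))
        y = _series(rng.normal(size=20))
        base = correlate(x, y).r
        assert correlate(3.0 * x + 7.0, 0.5 * y - 2.0).r == pytest.approx(base)

    def test_zero_variance_error(self):
        x = _series([1, 1, 1])
        y = _series([1, 2, 3])
        with pytest.raises(ValidationError):
            correlate(x, y)

    def test_too_short(self):
        with pytest.raises(ValidationError):
            correlate(_series([1, 2]), _series([3, 4]))


class TestContingency:
    def test_independence_identity(self):
        res = contingency_test([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        table = np.array([[12, 30], [25, 8], [7, 20]])
        a = contingency_test(table)
        b = contingency_test(table.T)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_fisher_small_expected_matches_hypergeom(self):
        # margins fix the 2x2 family; two-sided p sums pmf <= pmf(observed)
        table = np.array([[8, 2], [1, 5]])
        res = contingency_test(table)
        assert res.test_name == "fisher_exact"
        n = table.sum()
        r1, c1 = table.sum(axis=1)[0], table.sum(axis=0)[0]
        support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        pmf = {k: hypergeom.pmf(k, n, r1, c1) for k in support}
        p_enum = sum(p for p in pmf.values() if p <= pmf[table[0, 0]] + 1e-12)
        assert res.p_value == pytest.approx(p_enum)

    def test_zero_margin_error(self):
        with pytest.raises(ValidationError, match="margin"):
            contingency_test([[0, 0], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            contingency_test([[1.5, 2], [3, 4]])


class TestSideRatio:
    def test_planted_direction(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(40)]
        side = pd.Series(["left"] * 20 + ["right"] * 20, index=samples)
        scores = pd.DataFrame(
            rng.normal(size=(3, 40)), index=["up_left", "up_right", "flat"],
            columns=samples,
        )
        scores.loc["up_left", side == "left"] += 3.0
        scores.loc["up_right", side == "right"] += 3.0
        ratio = infiltration_side_ratio(scores, side)
        assert ratio["up_left"] > 1.0
        assert ratio["up_right"] < 1.0

    def test_single_side_error(self):
        samples = [f"s{i}" for i in range(4)]
        side = pd.Series(["left"] * 4, index=samples)
        scores = pd.DataFrame(np.ones((2, 4)), index=["a", "b"], columns=samples)
        with pytest.raises(ValidationError):
            infiltration_side_ratio(scores, side)
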