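"""Kaplan-Meier estimation, log-rank testing and univariate Cox regression.

Implemented directly on the risk-set definitions: the product-limit
estimator counts same-time censorings as at risk; the log-rank statistic
uses the hypergeometric variance; the Cox partial likelihood is maximized
by Newton iterations with the Efron correction for tied event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .data_io import ValidationError


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def probability_at(self, t: float) -> float:
        """S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    test_name: str = "logrank"


@dataclass(frozen=True)
class CoxResult:
    log_hr: float
    se: float
    p_value: float  # Wald, two-sided
    n: int
    n_events: int
    iterations: int

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.log_hr))


def _clean(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValidationError("times and events must be 1-d and aligned")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValidationError("survival times must be finite and >= 0")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("events must be 0 or 1")
    drop = (t == 0) & (e == 0)
    if drop.any():
        warnings.warn(
            f"dropping {int(drop.sum())} record(s) censored at time 0 (uninformative)",
            stacklevel=3,
        )
        t, e = t[~drop], e[~drop]
    if len(t) == 0:
        raise ValidationError("no usable survival records")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one stratum."""
    t, e = _clean(times, events)
    n = len(t)
    event_times = np.unique(t[e == 1])
    surv = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    d_counts = np.empty(len(event_times), dtype=int)
    s = 1.0
    for i, et in enumerate(event_times):
        n_i = int((t >= et).sum())
        d_i = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv[i], at_risk[i], d_counts[i] = s, n_i, d_i
    return KMCurve(event_times, surv, at_risk, d_counts, n_total=n)


def logrank_test(times, events, groups) -> TestResult:
    """k-stratum log-rank test (chi-square, k - 1 df)."""
    t, e = _clean(times, events)
    g = np.asarray(groups)
    if len(g) != len(np.asarray(times)):
        raise ValidationError("groups must align with times")
    # re-apply the same time-0 censor drop to the labels
    t_all = np.asarray(times, dtype=float)
    e_all = np.asarray(events, dtype=int)
    keep = ~((t_all == 0) & (e_all == 0))
    g = g[keep]
    levels = pd.unique(g)
    k = len(levels)
    if k < 2:
        raise ValidationError("log-rank needs >= 2 strata")
    for lv in levels:
        if (g == lv).sum() == 0:
            raise ValidationError(f"stratum {lv!r} has no subjects")
    if e.sum() == 0:
        raise ValidationError("log-rank needs >= 1 event")

    member = np.stack([(g == lv).astype(float) for lv in levels])  # k x n
    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n_i = at_risk.sum()
        d_i = ((t == et) & (e == 1)).sum()
        n_g = member[:, at_risk].sum(axis=1)
        o_g = member[:, (t == et) & (e == 1)].sum(axis=1)
        observed += o_g
        expected += d_i * n_g / n_i
        if n_i > 1:
            factor = d_i * (n_i - d_i) / (n_i - 1)
            p = n_g / n_i
            var += factor * (np.diag(p) - np.outer(p, p))
    diff = (observed - expected)[:-1]
    v = var[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, k - 1))
    return TestResult(stat, k - 1, p)


def _efron_quantities(t, e, x, beta):
    """Log partial likelihood, score and information at beta (Efron ties)."""
    order = np.argsort(-t, kind="stable")  # decreasing time
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    w = np.exp(eta)
    wx = w * x
    wxx = w * x * x
    # cumulative risk-set sums walking from the largest time down
    cs_w = np.cumsum(w)
    cs_wx = np.cumsum(wx)
    cs_wxx = np.cumsum(wxx)

    loglik = 0.0
    score = 0.0
    info = 0.0
    event_times = np.unique(t[e == 1])
    for et in event_times:
        in_risk = t >= et  # prefix of the sorted arrays
        last = int(in_risk.sum()) - 1
        r_w, r_wx, r_wxx = cs_w[last], cs_wx[last], cs_wxx[last]
        tied = (t == et) & (e == 1)
        d = int(tied.sum())
        d_w, d_wx, d_wxx = w[tied].sum(), wx[tied].sum(), wxx[tied].sum()
        s_x = x[tied].sum()
        loglik += beta * s_x
        for ell in range(d):
            f = ell / d
            phi = r_w - f * d_w
            m1 = r_wx - f * d_wx
            m2 = r_wxx - f * d_wxx
            loglik -= np.log(phi)
            score -= m1 / phi
            info += m2 / phi - (m1 / phi) ** 2
        score += s_x
    return loglik, score, info


def cox_score_test(times, events, covariate) -> TestResult:
    """Partial-likelihood score test at beta = 0 (equals log-rank when tie-free)."""
    t, e = _clean(times, events)
    x = np.asarray(covariate, dtype=float)
    t_all = np.asarray(times, dtype=float)
    e_all = np.asarray(events, dtype=int)
    keep = ~((t_all == 0) & (e_all == 0))
    x = x[keep]
    _, u, i = _efron_quantities(t, e, x, 0.0)
    if i <= 0:
        raise ValidationError("zero information at beta = 0")
    stat = float(u * u / i)
    return TestResult(stat, 1, float(chi2.sf(stat, 1)), test_name="cox_score")


def cox_univariate(
    times,
    events,
    covariate,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton iteration.

    Uses the Efron approximation for tied event times.  Raises on a
    non-converging or monotone partial likelihood (complete separation).
    """
    t, e = _clean(times, events)
    x = np.asarray(covariate, dtype=float)
    t_all = np.asarray(times, dtype=float)
    e_all = np.asarray(events, dtype=int)
    keep = ~((t_all == 0) & (e_all == 0))
    x = x[keep]
    if len(x) != len(t):
        raise ValidationError("covariate must align with times")
    if np.ptp(x) == 0:
        raise ValidationError("covariate has zero variance")
    if e.sum() == 0:
        raise ValidationError("Cox regression needs >= 1 event")

    # standardize internally for numerical stability; back-transform at the end
    scale = x.std()
    xs = (x - x.mean()) / scale

    beta = 0.0
    for it in range(1, max_iter + 1):
        _, u, i = _efron_quantities(t, e, xs, beta)
        if i <= 0:
            raise ValidationError("non-positive information; likelihood is degenerate")
        step = u / i
        beta_new = beta + np.clip(step, -5.0, 5.0)
        if abs(beta_new) > 50:
            raise ValidationError(
                "monotone partial likelihood (complete separation?); "
                "coefficient diverges"
            )
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise ValidationError(f"Newton iteration did not converge in {max_iter} steps")

    _, _, i = _efron_quantities(t, e, xs, beta)
    se_s = 1.0 / np.sqrt(i)
    log_hr = beta / scale
    se = se_s / scale
    z = log_hr / se
    p = float(2.0 * norm.sf(abs(z)))
    return CoxResult(float(log_hr), float(se), p, n=len(t), n_events=int(e.sum()), iterations=it)


def km_plot_window(
    curves: dict[str, KMCurve],
    t_max: float = 4000.0,
    path=None,
    ax=None,
    at_risk_table: bool = False,
):
    """Step-function KM plot truncated at ``t_max`` (display window only).

    Empty or None strata are skipped with a warning.  Returns the axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    drawn = 0
    for label, curve in curves.items():
        if curve is None or curve.n_total == 0:
            warnings.warn(f"stratum {label!r} is empty; excluded from plot", stacklevel=2)
            continue
        xs = np.concatenate([[0.0], curve.times])
        ys = np.concatenate([[1.0], curve.survival])
        inside = xs <= t_max
        xs, ys = xs[inside], ys[inside]
        if xs[-1] < t_max:  # hold the last in-window level out to the edge
            xs = np.append(xs, t_max)
            ys = np.append(ys, ys[-1])
        ax.step(xs, ys, where="post", label=str(label))
        drawn += 1
    ax.set_xlim(0, t_max)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    if drawn:
        ax.legend(frameon=False, fontsize=8)
    if at_risk_table and drawn:
        ticks = np.linspace(0, t_max, 5)
        lines = []
        for label, curve in curves.items():
            if curve is None or curve.n_total == 0:
                continue
            counts = [
                int(np.sum(curve.at_risk[curve.times >= tk].max() if np.any(curve.times >= tk) else 0))
                for tk in ticks
            ]
            lines.append(f"{label}: " + " ".join(str(c) for c in counts))
        ax.text(0.02, 0.02, "\n".join(lines), transform=ax.transAxes, fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
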