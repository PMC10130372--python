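"""Cohort-level outcome statistics.

ROC (Youden) dichotomization of continuous quantifications, Pearson χ² on
the 2×2 heterogeneity × recurrence table, the Kaplan–Meier product-limit
estimator, the two-group log-rank test, a single-covariate Cox
proportional-hazards fit (Breslow partial likelihood, Newton–Raphson with
analytic score and information), and the Xu–O'Quigley explained-randomness
measure ρ² = 1 − exp(−LR/k) that summarises a Cox fit on a small cohort
more stably than its p-value.

The survival machinery is implemented directly (a one-dimensional Breslow
Newton solver is a few dozen lines and is exercised against an independent
grid-search oracle and against lifelines in the test suite); everything
else delegates to scipy where a standard routine exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocResult",
    "ChiSquareResult",
    "SurvivalFit",
    "KaplanMeierEstimate",
    "LogRankResult",
    "ReproducibilityResult",
    "roc_cutoff",
    "chi_square_2x2",
    "km_estimate",
    "log_rank",
    "cox_fit",
    "cox_loglik",
    "rho2_xoq",
    "heterogeneity_table",
    "median_split",
    "reproducibility",
]


# ---------------------------------------------------------------------------
# dichotomization and contingency statistics


@dataclass
class RocResult:
    cutoff: float
    youden_j: float
    sens: float
    spec: float


def roc_cutoff(values, labels) -> RocResult:
    """ROC-derived dichotomization cutoff maximising Youden's J.

    Scans the midpoints between consecutive sorted unique values; a value
    is called positive when it is at/above the cutoff. Ties in J are
    broken toward the lower cutoff (higher sensitivity).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be matched 1-D sequences")
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both outcome classes must be present for ROC analysis")
    uniq = np.unique(values)
    if uniq.size == 1:
        cut = float(uniq[0])  # everything called positive: J = 0
        return RocResult(cutoff=cut, youden_j=0.0, sens=1.0, spec=0.0)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for c in cuts:  # ascending, so ties keep the lower cutoff
        called = values >= c
        sens = float(called[pos].mean())
        spec = float((~called[neg]).mean())
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = RocResult(cutoff=float(c), youden_j=j, sens=sens, spec=spec)
    return best


@dataclass
class ChiSquareResult:
    table: np.ndarray
    statistic: float
    p: float


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson χ² (1 df, no continuity correction) on a 2×2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2×2 with nonnegative counts")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: χ² undefined")
    n = table.sum()
    expected = np.outer(row, col) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return ChiSquareResult(table=table.astype(int), statistic=stat, p=max(p, np.nextafter(0, 1)))


def heterogeneity_table(het_flags, events) -> ChiSquareResult:
    """χ² association between cluster-type heterogeneity (≥ 2 types) and
    recurrence. Rows: heterogeneous / not; columns: recurrence / not.
    Specimens with unknown outcome must be excluded before calling."""
    het = np.asarray(het_flags, dtype=bool)
    ev = np.asarray(events, dtype=int)
    if het.shape != ev.shape:
        raise ValueError("het_flags and events must be matched")
    table = [
        [int((het & (ev == 1)).sum()), int((het & (ev == 0)).sum())],
        [int((~het & (ev == 1)).sum()), int((~het & (ev == 0)).sum())],
    ]
    return chi_square_2x2(table)


def median_split(values) -> np.ndarray:
    """High/low labels at the median: ``high`` iff value > median, ties at
    the median sent to low (so ⌈n/2⌉ specimens land in the low group for
    distinct values)."""
    values = np.asarray(values, dtype=float)
    return values > np.median(values)


# ---------------------------------------------------------------------------
# survival estimation


@dataclass
class KaplanMeierEstimate:
    """Product-limit survival curve with right censoring."""

    event_times: np.ndarray  # distinct times with >= 1 event
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t); right-continuous step function, S = 1 before the first
        event."""
        i = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimate(times, events) -> KaplanMeierEstimate:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("at least one subject required")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e == 1])
    at_risk = np.empty(uniq.size, dtype=int)
    d = np.empty(uniq.size, dtype=int)
    for i, u in enumerate(uniq):
        at_risk[i] = int((t >= u).sum())
        d[i] = int(((t == u) & (e == 1)).sum())
    surv = np.cumprod(1.0 - d / at_risk) if uniq.size else np.array([])
    return KaplanMeierEstimate(event_times=uniq, survival=surv, n_at_risk=at_risk, n_events=d)


@dataclass
class LogRankResult:
    statistic: float
    p: float


def log_rank(group_a, group_b) -> LogRankResult:
    """Two-group log-rank test; each group is ``(times, events)``.

    Tied event times are handled by simultaneous risk-set accounting with
    the hypergeometric variance; the statistic is referred to χ²(1).
    """
    ta, ea = (np.asarray(v, dtype=float) for v in group_a)
    tb, eb = (np.asarray(v, dtype=float) for v in group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if event_times.size == 0:
        return LogRankResult(statistic=0.0, p=1.0)
    ta_sorted = np.sort(ta)
    tb_sorted = np.sort(tb)
    na = ta.size - np.searchsorted(ta_sorted, event_times, side="left")
    nb = tb.size - np.searchsorted(tb_sorted, event_times, side="left")
    da = np.array([((ta == u) & (ea == 1)).sum() for u in event_times], dtype=float)
    db = np.array([((tb == u) & (eb == 1)).sum() for u in event_times], dtype=float)
    n = (na + nb).astype(float)
    d = da + db
    expected = d * na / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (na / n) * (nb / n) * (n - d) / (n - 1)
    var = np.where(n > 1, var, 0.0)
    v_sum = float(var.sum())
    if v_sum == 0.0:
        return LogRankResult(statistic=0.0, p=1.0)
    stat = float((da - expected).sum() ** 2 / v_sum)
    return LogRankResult(statistic=stat, p=float(sps.chi2.sf(stat, df=1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate, Breslow ties)


@dataclass
class SurvivalFit:
    beta_hat: float
    se: float
    lr_stat: float
    n_events: int
    rho2_xoq: float
    converged: bool = True
    separation: bool = False


def _cox_arrays(times, events, covariate):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if not (times.shape == events.shape == x.shape) or times.ndim != 1:
        raise ValueError("times, events and covariate must be matched 1-D sequences")
    order = np.argsort(times, kind="stable")
    return times[order], events[order], x[order]


def cox_loglik(times, events, covariate, beta: float):
    """Breslow partial log-likelihood and its first two derivatives."""
    t, e, x = _cox_arrays(times, events, covariate)
    r = np.exp(beta * x)
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((x * r)[::-1])[::-1]
    s2 = np.cumsum((x * x * r)[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")  # risk set starts at first tie
    idx = first[e == 1]
    xi = x[e == 1]
    mean = s1[idx] / s0[idx]
    ll = float(np.sum(beta * xi - np.log(s0[idx])))
    score = float(np.sum(xi - mean))
    info = float(np.sum(s2[idx] / s0[idx] - mean**2))
    return ll, score, info


def cox_fit(times, events, covariate, tol: float = 1e-8, max_iter: int = 50) -> SurvivalFit:
    """Single-covariate Cox PH fit by Newton iteration on the Breslow
    partial likelihood.

    Returns the MLE β̂, its standard error from the inverse observed
    information, the likelihood-ratio statistic 2(ℓ(β̂) − ℓ(0)), the event
    count, and ρ²XOQ computed on the events-based scale. A monotone
    partial likelihood (complete separation) is reported with
    ``separation=True`` and β̂ clipped at the search bound.
    """
    t, e, x = _cox_arrays(times, events, covariate)
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events observed: partial likelihood is flat")
    at_risk_x = x  # constancy check: covariate must vary
    if np.ptp(at_risk_x) == 0:
        raise ValueError("constant covariate: Cox model unidentifiable")

    beta = 0.0
    ll0, _, _ = cox_loglik(t, e, x, 0.0)
    ll = ll0
    converged = False
    separation = False
    bound = 30.0
    for _ in range(max_iter):
        ll, score, info = cox_loglik(t, e, x, beta)
        if abs(score) < tol:
            converged = True
            break
        if info <= 0:
            separation = True
            break
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        new_beta = beta + step
        if abs(new_beta) >= bound:
            separation = True
            beta = float(np.clip(new_beta, -bound, bound))
            break
        beta = new_beta
    ll, score, info = cox_loglik(t, e, x, beta)
    if abs(beta) >= 15.0:  # numerically flat likelihood: monotone in beta
        separation = True
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    lr = max(0.0, 2.0 * (ll - ll0))
    return SurvivalFit(
        beta_hat=float(beta),
        se=se,
        lr_stat=lr,
        n_events=n_events,
        rho2_xoq=rho2_xoq(lr, n_events),
        converged=converged,
        separation=separation,
    )


def rho2_xoq(lr_stat: float, n_events: int, variant: str = "events", n_total: int | None = None) -> float:
    """Explained randomness ρ² = 1 − exp(−LR / k).

    ``variant="events"`` (default) normalises by the number of observed
    events, the recommended choice under censoring; ``variant="n"``
    divides by the total sample size instead (``n_total``).
    """
    if lr_stat < 0:
        raise ValueError("likelihood-ratio statistic must be nonnegative")
    if variant == "events":
        k = n_events
    elif variant == "n":
        k = n_total if n_total is not None else n_events
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    if k is None or k < 1:
        raise ValueError("normalising count must be >= 1")
    return float(1.0 - np.exp(-lr_stat / k))


# ---------------------------------------------------------------------------
# reproducibility between repeat runs


@dataclass
class ReproducibilityResult:
    correlations: dict  # Spearman rho per shared quantification
    concordance: float  # fraction of specimens with identical heterogeneity flags
    n_matched: int


def reproducibility(run1, run2, het_col: str = "heterogeneous") -> ReproducibilityResult:
    """Between-run agreement of per-specimen quantifications.

    ``run1`` and ``run2`` are DataFrames indexed by specimen id (or with a
    ``specimen_id`` column). Spearman correlations are reported per shared
    numeric column when at least 3 specimens match; the heterogeneity-flag
    concordance is always reported.
    """
    import pandas as pd

    def _prep(df):
        df = pd.DataFrame(df)
        if "specimen_id" in df.columns:
            df = df.set_index("specimen_id")
        return df

    a, b = _prep(run1), _prep(run2)
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    n = len(common)
    correlations: dict = {}
    if n >= 3:
        for col in a.columns.intersection(b.columns):
            if col == het_col or not np.issubdtype(a[col].dtype, np.number):
                continue
            rho = sps.spearmanr(a[col], b[col]).statistic
            correlations[col] = float(rho)
    if het_col in a.columns and het_col in b.columns and n > 0:
        concordance = float((a[het_col].astype(bool).values == b[het_col].astype(bool).values).mean())
    else:
        concordance = float("nan")
    return ReproducibilityResult(correlations=correlations, concordance=concordance, n_matched=n)
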