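"""Kaplan–Meier estimation, Greenwood confidence bands and the two-group
log-rank test, written from first principles.

Conventions: the product-limit estimator is right-continuous; censored
observations tied with an event time stay in that time's risk set
(censoring happens after events at ties, matching Breslow tie handling in
the Cox module); confidence bands use the complementary log-log transform
so they remain inside [0, 1].
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from radsurv.cohort import Cohort
from radsurv.stratify import BinaryFactor

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray      # distinct event times, ascending
    n_risk: np.ndarray     # at-risk counts just before each event time
    n_events: np.ndarray   # events at each time
    survival: np.ndarray   # S(t_j), right-continuous step heights
    greenwood_var: np.ndarray  # Greenwood variance of S(t_j)
    n: int                 # sample size

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S(0) = 1)."""
        j = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if j < 0 else float(self.survival[j])

    def median_survival(self) -> float:
        """Smallest event time with S(t) <= 0.5 (NaN if never reached)."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else float("nan")


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimate from right-censored data."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("empty input")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if not (time > 0).all():
        raise ValueError("all times must be > 0")

    event_times = np.unique(time[event == 1])
    n_risk = np.array([(time >= t).sum() for t in event_times], dtype=int)
    d = np.array([((time == t) & (event == 1)).sum() for t in event_times],
                 dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / n_risk
        surv = np.cumprod(frac)
        inc = np.where(n_risk > d, d / (n_risk * (n_risk - d)), 0.0)
        gw = surv**2 * np.cumsum(inc)
    return KMCurve(event_times, n_risk, d, surv, gw, n=time.size)


def greenwood_ci(curve: KMCurve, level: float = 0.95):
    """Complementary log-log Greenwood confidence bands, clipped to [0, 1].

    Where S = 1 the band is the degenerate [1, 1]; where S = 0 it is [0, 0].
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    S = curve.survival
    lower = np.empty_like(S)
    upper = np.empty_like(S)
    # cumulative Greenwood sum sum d/(n(n-d)), recovered from the variance
    with np.errstate(divide="ignore", invalid="ignore"):
        csum = np.where(S > 0, curve.greenwood_var / S**2, np.inf)
        for j, s in enumerate(S):
            if s >= 1.0:
                lower[j] = upper[j] = 1.0
            elif s <= 0.0:
                lower[j] = upper[j] = 0.0
            else:
                se_cll = np.sqrt(csum[j]) / abs(np.log(s))
                lower[j] = s ** np.exp(z * se_cll)
                upper[j] = s ** np.exp(-z * se_cll)
    return np.clip(lower, 0, 1), np.clip(upper, 0, 1)


@dataclasses.dataclass
class LogRankResult:
    """Two-group log-rank test over the pooled distinct event times."""

    statistic: float
    p_value: float
    df: int
    observed: dict[str, float]
    expected: dict[str, float]

    def display_p(self) -> str:
        """p to 2 significant figures, floored at '<0.0001'."""
        if self.p_value < 1e-4:
            return "<0.0001"
        return f"{self.p_value:.2g}"


def logrank_test(time, event, group) -> LogRankResult:
    """Standard two-group log-rank test (hypergeometric variance)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist(), key=str)
    if len(levels) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(levels)}")
    g1 = group == levels[0]
    if event.sum() < 1:
        raise ValueError("need at least one event")

    O1 = E1 = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        nj = int(at_risk.sum())
        n1j = int((at_risk & g1).sum())
        dj = int(((time == t) & (event == 1)).sum())
        d1j = int(((time == t) & (event == 1) & g1).sum())
        O1 += d1j
        E1 += dj * n1j / nj
        if nj > 1:
            V += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    d_total = float(event.sum())
    if V <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = (O1 - E1) ** 2 / V
        p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(
        statistic=float(stat), p_value=p, df=1,
        observed={str(levels[0]): O1, str(levels[1]): d_total - O1},
        expected={str(levels[0]): E1, str(levels[1]): d_total - E1},
    )


@dataclasses.dataclass
class PanelRecord:
    """One Kaplan–Meier comparison panel: per-group curves + log-rank."""

    name: str
    grouping: str
    group_stats: pd.DataFrame  # group, n, events, median_survival
    curves: dict[str, KMCurve]
    logrank: LogRankResult

    def to_row(self) -> dict:
        row = {"panel": self.name, "grouping": self.grouping,
               "statistic": self.logrank.statistic,
               "p_value": self.logrank.p_value,
               "p_display": self.logrank.display_p()}
        for _, g in self.group_stats.iterrows():
            lbl = g["group"]
            row[f"n[{lbl}]"] = int(g["n"])
            row[f"events[{lbl}]"] = int(g["events"])
            row[f"median_survival[{lbl}]"] = g["median_survival"]
        return row


def _extract_time_event(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, Cohort):
        return data.time, data.event
    return (np.asarray(data["time"], float), np.asarray(data["event"], int))


def compare_strata(
    data,
    grouping: BinaryFactor,
    within: np.ndarray | None = None,
    name: str | None = None,
) -> PanelRecord | None:
    """Kaplan–Meier curves and log-rank test for one binary grouping,
    optionally restricted to a stratum cell (boolean mask or index array).

    Returns None (with a log entry) if either group is empty after the
    restriction, mirroring a skipped figure panel.
    """
    time, event = _extract_time_event(data)
    labels = grouping.labels
    if within is not None:
        within = np.asarray(within)
        if within.dtype == bool:
            within = np.flatnonzero(within)
        time, event, labels = time[within], event[within], labels[within]
    stats_rows = []
    curves = {}
    for lv in grouping.levels:
        m = labels == lv
        if not m.any():
            logger.warning("panel %r skipped: group %r empty after restriction",
                           name or grouping.name, lv)
            return None
        curve = km_estimate(time[m], event[m])
        curves[lv] = curve
        stats_rows.append({"group": lv, "n": int(m.sum()),
                           "events": int(event[m].sum()),
                           "median_survival": curve.median_survival()})
    lr = logrank_test(time, event, labels)
    return PanelRecord(
        name=name or grouping.name, grouping=grouping.name,
        group_stats=pd.DataFrame(stats_rows), curves=curves, logrank=lr)
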