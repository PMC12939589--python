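"""Redundancy analysis among top-ranked features.

Top-ranked biomarkers from stability selection are frequently strongly
inter-correlated (the same prognostic signal surfacing through several
feature families).  This module quantifies that redundancy with the
Spearman rank correlation matrix, scores each candidate by its
representativeness strength score — RSS(f) = mean over g≠f of |ρ(f, g)| —
and picks the candidate with maximal RSS as the single representative
biomarker for downstream stratification.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from radsurv.cohort import Cohort
from radsurv.ranking import FrequencyTable

logger = logging.getLogger(__name__)

DEFAULT_REDUNDANCY_THRESHOLD = 0.6


def spearman_matrix(data, features: list[str] | None = None) -> pd.DataFrame:
    """Spearman rank correlation matrix (average ranks for ties).

    ``data`` may be a Cohort or a DataFrame.  A zero-variance feature has
    undefined correlations; its entries are NaN and a warning is logged.
    """
    df = data.features if isinstance(data, Cohort) else data
    if features is not None:
        df = df[list(features)]
    if df.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    X = df.to_numpy(float)
    const = X.std(axis=0) == 0
    if const.any():
        logger.warning("zero-variance features have undefined correlations: %s",
                       list(df.columns[const]))
    with np.errstate(invalid="ignore"):
        rho, _ = stats.spearmanr(X)
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-feature case
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def compute_rss(rho: pd.DataFrame, feature: str) -> float:
    """Representativeness strength score: mean |ρ| with the other set members."""
    if feature not in rho.index:
        raise KeyError(f"{feature!r} not in the correlation matrix")
    if len(rho) < 2:
        raise ValueError("RSS is undefined for a singleton set")
    others = [f for f in rho.index if f != feature]
    return float(np.abs(rho.loc[feature, others].to_numpy(float)).mean())


@dataclasses.dataclass
class CorrelationReport:
    """Spearman matrix, RSS scores and the chosen representative for a
    candidate set of top-ranked features."""

    features: list[str]
    rho: pd.DataFrame
    rss: pd.Series
    representative: str
    threshold: float = DEFAULT_REDUNDANCY_THRESHOLD

    @property
    def redundant_pairs(self) -> list[tuple[str, str, float]]:
        """Feature pairs with |ρ| at or above the redundancy threshold."""
        out = []
        for i, f in enumerate(self.features):
            for g in self.features[i + 1:]:
                r = float(self.rho.loc[f, g])
                if np.isfinite(r) and abs(r) >= self.threshold:
                    out.append((f, g, r))
        return out

    def to_csv(self, matrix_path, record_path=None) -> None:
        self.rho.to_csv(matrix_path)
        if record_path is not None:
            pd.DataFrame({
                "feature": self.features,
                "rss": [self.rss[f] for f in self.features],
                "representative": [f == self.representative for f in self.features],
            }).to_csv(record_path, index=False)


def select_representative(
    freq: FrequencyTable,
    cohort: Cohort,
    candidates: list[str] | int | None = None,
    *,
    threshold: float = DEFAULT_REDUNDANCY_THRESHOLD,
) -> tuple[str, CorrelationReport]:
    """Choose the representative biomarker among top-ranked candidates.

    RSS exists to resolve ties: when several features share the maximal
    selection count, the one with maximal RSS within that tie group is
    chosen (ties break by higher selection count, then name).  When the
    rank-1 feature is a singleton there is nothing to resolve — it is the
    representative outright, and the correlation report is computed over
    the top-k (k = 5, mirroring a five-way tie) for context.  An explicit
    feature list or integer k overrides the tie-group logic.
    """
    forced_rep: str | None = None
    if isinstance(candidates, list):
        cand = list(candidates)
    else:
        k = candidates if isinstance(candidates, int) else 5
        tie = freq.top_tie_group()
        if not isinstance(candidates, int) and len(tie) >= 2:
            cand = tie
        else:
            cand = list(freq.top(k)["feature"])
            if not isinstance(candidates, int) and len(tie) == 1:
                forced_rep = tie[0]  # unambiguous rank-1 winner
    if not cand:
        raise ValueError("empty candidate set")
    if len(cand) == 1:
        raise ValueError("RSS-based selection needs >= 2 candidates")

    rho = spearman_matrix(cohort, cand)
    rss = pd.Series({f: compute_rss(rho, f) for f in cand})
    counts = dict(zip(freq.table["feature"], freq.table["count"]))
    order = sorted(cand, key=lambda f: (-rss[f], -counts.get(f, 0), f))
    rep = forced_rep if forced_rep is not None else order[0]
    if rss[rep] < threshold:
        logger.warning(
            "low redundancy: best RSS %.3f is below the |rho| >= %.2f flag; "
            "the candidate set shares little signal", rss[rep], threshold)
    report = CorrelationReport(cand, rho, rss, rep, threshold)
    return rep, report
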