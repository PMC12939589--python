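"""Patient-table data model: container, CSV round-trip, and cohort summary.

A cohort couples a radiomic feature matrix (107 features in seven
categories in the reference layout) with demographic covariates
(age in years, gender, overall stage I/II/IIIa/IIIb) and the
right-censored outcome (follow-up time in years, event indicator).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven radiomic feature categories with the feature count of the
#: standard 107-feature extraction (first-order statistics, shape, and the
#: five texture-matrix families).
FEATURE_CATEGORIES: dict[str, int] = {
    "FirstOrder": 18,
    "Shape": 14,
    "GLCM": 24,
    "GLSZM": 16,
    "GLRLM": 16,
    "NGTDM": 5,
    "GLDM": 14,
}

STAGES = ("I", "II", "IIIa", "IIIb")
GENDERS = ("female", "male")

_META_COLS = ("patient_id", "age", "gender", "stage", "time", "event")

DAYS_PER_YEAR = 365.25


class CohortError(ValueError):
    """Raised when a patient table violates the cohort contract."""


def _canonical_stage(token: str) -> str:
    t = str(token).strip().lower()
    for s in STAGES:
        if t == s.lower():
            return s
    raise CohortError(f"unknown stage token {token!r}; expected one of {STAGES}")


def _canonical_gender(token: str) -> str:
    t = str(token).strip().lower()
    if t in ("female", "f"):
        return "female"
    if t in ("male", "m"):
        return "male"
    raise CohortError(f"unknown gender token {token!r}; expected male/female")


@dataclasses.dataclass
class Cohort:
    """A validated patient-by-feature survival table.

    Parameters
    ----------
    data:
        One row per patient with columns ``patient_id``, one column per
        radiomic feature, ``age`` (years), ``gender``, ``stage``, ``time``
        (years, > 0) and ``event`` (1 = death, 0 = censored).
    feature_categories:
        Mapping feature name -> category label; its keys define which
        columns of ``data`` are features.
    """

    data: pd.DataFrame
    feature_categories: Mapping[str, str]

    def __post_init__(self) -> None:
        self.feature_categories = dict(self.feature_categories)
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.feature_categories)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    @property
    def age(self) -> np.ndarray:
        return self.data["age"].to_numpy(float)

    @property
    def gender(self) -> pd.Series:
        return self.data["gender"]

    @property
    def stage(self) -> pd.Series:
        return self.data["stage"]

    @property
    def categories(self) -> list[str]:
        seen: list[str] = []
        for c in self.feature_categories.values():
            if c not in seen:
                seen.append(c)
        return seen

    def validate(self) -> None:
        df = self.data
        missing_cols = [c for c in _META_COLS if c not in df.columns]
        if missing_cols:
            raise CohortError(f"missing required columns: {missing_cols}")
        feats = self.feature_names
        if len(feats) != len(set(feats)):
            raise CohortError("feature names are not unique")
        absent = [f for f in feats if f not in df.columns]
        if absent:
            raise CohortError(f"features absent from table: {absent[:5]}")
        null = df[list(_META_COLS) + feats].isna()
        if null.to_numpy().any():
            rows, cols = np.nonzero(null.to_numpy())
            pid = df["patient_id"].iloc[rows[0]]
            col = null.columns[cols[0]]
            raise CohortError(
                f"missing value for patient {pid!r}, column {col!r} "
                f"({null.to_numpy().sum()} missing cells total)"
            )
        if df["patient_id"].duplicated().any():
            raise CohortError("patient_id values are not unique")
        if len(df) and not (df["time"].to_numpy(float) > 0).all():
            raise CohortError("all survival times must be > 0")
        if len(df):
            X = df[feats].to_numpy(float)
            if not np.isfinite(X).all():
                raise CohortError("non-finite feature value encountered")
            if (X < 0).any():
                raise CohortError("feature values must be non-negative")
        if not set(df["event"].unique()).issubset({0, 1}):
            raise CohortError("event must be 0 (censored) or 1 (death)")
        df["stage"] = df["stage"].map(_canonical_stage)
        df["gender"] = df["gender"].map(_canonical_gender)
        n_cat = len(set(self.feature_categories.values()))
        if feats and n_cat > 7:
            raise CohortError(f"feature categories must form at most 7 groups, got {n_cat}")

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row-subset by boolean mask or integer index array."""
        return Cohort(self.data.iloc[np.asarray(mask)].reset_index(drop=True),
                      self.feature_categories)


@dataclasses.dataclass
class CohortSummary:
    """Baseline descriptive statistics of a cohort (demographics table)."""

    n: int
    age_mean: float
    age_sd: float
    age_median: float
    age_iqr: tuple[float, float]
    gender_counts: dict[str, int]
    gender_pct: dict[str, float]
    stage_counts: dict[str, int]
    stage_pct: dict[str, float]
    time_median: float
    time_range: tuple[float, float]
    n_events: int
    n_censored: int
    event_pct: float
    censored_pct: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Number of patients (N)", f"{self.n}"),
            ("Age, mean ± SD (years)", f"{self.age_mean:.1f} ± {self.age_sd:.1f}"),
            ("Age, median [IQR] (years)",
             f"{self.age_median:.1f} ({self.age_iqr[0]:.1f}–{self.age_iqr[1]:.1f})"),
        ]
        for g in GENDERS:
            rows.append((f"Gender: {g}, n (%)",
                         f"{self.gender_counts.get(g, 0)} ({self.gender_pct.get(g, 0.0):.1f}%)"))
        for s in STAGES:
            rows.append((f"Stage {s}, n (%)",
                         f"{self.stage_counts.get(s, 0)} ({self.stage_pct.get(s, 0.0):.1f}%)"))
        rows.append(("Survival time, median (range) (years)",
                     f"{self.time_median:.2f} ({self.time_range[0]:.2f}–{self.time_range[1]:.2f})"))
        rows.append(("Event status: Death, n (%)", f"{self.n_events} ({self.event_pct:.1f}%)"))
        rows.append(("Event status: Censored, n (%)",
                     f"{self.n_censored} ({self.censored_pct:.1f}%)"))
        return pd.DataFrame(rows, columns=["Characteristic", "Value"])


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Compute the baseline demographic/clinical characteristics table."""
    age = cohort.age
    time = cohort.time
    event = cohort.event
    n = cohort.n
    if n == 0:
        raise CohortError("cannot summarize an empty cohort")
    gc = cohort.gender.value_counts().to_dict()
    sc = cohort.stage.value_counts().to_dict()
    n_events = int(event.sum())
    q1, q3 = np.percentile(age, [25, 75])
    return CohortSummary(
        n=n,
        age_mean=float(np.mean(age)),
        age_sd=float(np.std(age, ddof=1)) if n > 1 else 0.0,
        age_median=float(np.median(age)),
        age_iqr=(float(q1), float(q3)),
        gender_counts={k: int(v) for k, v in gc.items()},
        gender_pct={k: 100.0 * v / n for k, v in gc.items()},
        stage_counts={k: int(v) for k, v in sc.items()},
        stage_pct={k: 100.0 * v / n for k, v in sc.items()},
        time_median=float(np.median(time)),
        time_range=(float(time.min()), float(time.max())),
        n_events=n_events,
        n_censored=n - n_events,
        event_pct=100.0 * n_events / n,
        censored_pct=100.0 * (n - n_events) / n,
    )


def _default_schema(columns: Sequence[str]) -> dict[str, str]:
    """Infer feature->category from ``<Category>_<name>`` column names."""
    schema = {}
    for c in columns:
        if c in _META_COLS:
            continue
        cat = c.split("_", 1)[0] if "_" in c else "NGTDM" if c in NGTDM_FEATURES else None
        if cat not in FEATURE_CATEGORIES:
            raise CohortError(
                f"cannot infer category for column {c!r}; pass an explicit schema"
            )
        schema[c] = cat
    return schema


#: Real names of the five neighborhood gray-tone difference matrix features.
NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def read_schema(path: str | Path) -> dict[str, str]:
    """Read a two-column (feature, category) CSV into a schema mapping."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise CohortError("schema CSV must have columns feature,category")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_schema(schema: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"feature": list(schema), "category": [schema[f] for f in schema]}
    ).to_csv(path, index=False)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
    time_in_days: bool = False,
) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    schema:
        feature -> category mapping; if omitted, inferred from
        ``Category_name`` column prefixes.
    strict:
        If True (default), a missing cell raises naming the patient and
        column; if False, offending rows are dropped with a log entry.
    time_in_days:
        If the ``time`` column is recorded in days, convert to years.
    """
    df = pd.read_csv(path)
    if schema is None:
        schema = _default_schema(df.columns)
    cols = list(_META_COLS) + [f for f in schema if f in df.columns]
    null = df[[c for c in cols if c in df.columns]].isna()
    if null.to_numpy().any():
        rows = np.nonzero(null.any(axis=1).to_numpy())[0]
        if strict:
            r = rows[0]
            col = null.columns[np.nonzero(null.iloc[r].to_numpy())[0][0]]
            pid = df["patient_id"].iloc[r] if "patient_id" in df else f"row {r}"
            raise CohortError(f"missing value for patient {pid!r}, column {col!r}")
        logger.warning("dropping %d rows with missing values", len(rows))
        df = df.drop(index=df.index[rows]).reset_index(drop=True)
    if time_in_days:
        df["time"] = df["time"].astype(float) / DAYS_PER_YEAR
    return Cohort(df, schema)


def write_cohort(cohort: Cohort, path: str | Path, sidecar: str | None = None) -> None:
    """Write a cohort as CSV (optionally with a sidecar provenance note)."""
    cols = ["patient_id"] + cohort.feature_names + ["age", "gender", "stage", "time", "event"]
    cohort.data[cols].to_csv(path, index=False)
    if sidecar is not None:
        Path(str(path) + ".meta.txt").write_text(sidecar)
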