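"""Binary data mapping and hierarchical subgroup construction.

Each clinical or biomarker axis is dichotomized into a two-level factor —
stage I/II vs IIIa/IIIb, age and biomarker at the sample median (values at
or below the median go to the low group), gender as recorded — and factors
are crossed into a stratum set whose cells partition the cohort (the data
behind a patient-count heatmap).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from radsurv.cohort import Cohort, _canonical_stage, _canonical_gender


@dataclasses.dataclass
class BinaryFactor:
    """A two-level patient labeling with the threshold that produced it."""

    name: str
    labels: np.ndarray  # one label string per patient
    levels: tuple[str, str]  # (low-risk-ish label, high label)
    threshold: float | str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(self.levels)
        if bad:
            raise ValueError(f"labels outside declared levels: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def mask(self, level: str) -> np.ndarray:
        if level not in self.levels:
            raise ValueError(f"{level!r} is not a level of factor {self.name!r}")
        return self.labels == level

    def counts(self) -> dict[str, int]:
        return {lv: int((self.labels == lv).sum()) for lv in self.levels}


def binarize_by_median(
    values: Sequence[float],
    labels: tuple[str, str] = ("Low", "High"),
    name: str = "biomarker",
) -> BinaryFactor:
    """Median split: values <= median -> low label, > median -> high label.

    The <=-median convention puts ties at the cut in the low group and,
    for an even sample with distinct values, yields an exact 50/50 split.
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values to split at the median")
    med = float(np.median(v))
    if np.all(v == v[0]):
        raise ValueError("all values identical: no median split possible")
    lab = np.where(v <= med, labels[0], labels[1]).astype(object)
    return BinaryFactor(name=name, labels=lab, levels=labels, threshold=med)


def binarize_age(ages: Sequence[float]) -> BinaryFactor:
    """Median split of age into Young (<= median) and Old (> median)."""
    return binarize_by_median(ages, labels=("Young", "Old"), name="age")


def binarize_stage(stages: Sequence[str]) -> BinaryFactor:
    """Stage mapping: I and II -> Low; IIIa and IIIb -> High."""
    canon = [_canonical_stage(s) for s in stages]
    lab = np.array(
        ["Low" if s in ("I", "II") else "High" for s in canon], dtype=object)
    return BinaryFactor(name="stage", labels=lab, levels=("Low", "High"),
                        threshold="I/II vs IIIa/IIIb")


def binarize_gender(genders: Sequence[str]) -> BinaryFactor:
    """Gender as a two-level factor (Female, Male)."""
    canon = [_canonical_gender(g) for g in genders]
    lab = np.array(["Female" if g == "female" else "Male" for g in canon],
                   dtype=object)
    return BinaryFactor(name="gender", labels=lab, levels=("Female", "Male"))


def biomarker_factor(cohort: Cohort, feature: str) -> BinaryFactor:
    """Median split of one radiomic feature on a cohort."""
    f = binarize_by_median(cohort.data[feature].to_numpy(float),
                           labels=("Low", "High"), name=f"biomarker:{feature}")
    return f


@dataclasses.dataclass
class StratumSet:
    """Cells of the cross-classification of an ordered list of factors."""

    factor_names: list[str]
    cells: dict[tuple[str, ...], np.ndarray]  # label tuple -> row indices
    n: int

    def counts_frame(self) -> pd.DataFrame:
        """Long-format counts table (one row per cell)."""
        rows = []
        for key, idx in self.cells.items():
            rows.append(dict(zip(self.factor_names, key), count=len(idx)))
        return pd.DataFrame(rows)

    def cell(self, *labels: str) -> np.ndarray:
        return self.cells[tuple(labels)]


def build_strata(cohort_or_n, factors: Sequence[BinaryFactor]) -> StratumSet:
    """Cross the factors into a stratum set partitioning the cohort.

    Only non-empty cells are materialized; cells are enumerated in the
    level order of each factor, first factor varying slowest.
    """
    n = cohort_or_n.n if isinstance(cohort_or_n, Cohort) else int(cohort_or_n)
    for f in factors:
        if len(f) != n:
            raise ValueError(
                f"factor {f.name!r} labels {len(f)} patients, cohort has {n}")
    if not factors:
        return StratumSet([], {(): np.arange(n)}, n)

    cells: dict[tuple[str, ...], np.ndarray] = {}

    def recurse(prefix: tuple[str, ...], mask: np.ndarray, remaining):
        if not remaining:
            idx = np.flatnonzero(mask)
            if idx.size:
                cells[prefix] = idx
            return
        f = remaining[0]
        for lv in f.levels:
            recurse(prefix + (lv,), mask & f.mask(lv), remaining[1:])

    recurse((), np.ones(n, dtype=bool), list(factors))
    return StratumSet([f.name for f in factors], cells, n)
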