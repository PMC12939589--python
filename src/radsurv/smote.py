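"""Survival-aware SMOTE balancing of stratified subgroups.

Synthetic minority over-sampling adapted to rows that carry a
right-censored outcome: synthesis happens separately within each
(class × event-status) stratum, so an interpolated row inherits an
unambiguous event indicator and the censoring structure of its class is
preserved.  Feature vectors, survival time and age are interpolated
between a seed row and one of its k nearest minority neighbors with a
shared uniform weight; categorical covariates copy from the seed parent.

Balanced sets are for exploratory, comparative stratification only: they
never feed the feature-ranking or representative-selection stages.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

_NON_FEATURE_COLS = ("patient_id", "age", "gender", "stage", "time", "event")
#: numeric columns interpolated with the same weight as the features
_INTERP_COLS = ("time", "age")


@dataclasses.dataclass
class SmoteConfig:
    """Balancing parameters.

    target ``"majority"`` equalizes every class to the largest class;
    an explicit mapping gives per-class target sizes.  ``strata_mode``
    ``"within-event-status"`` (default) synthesizes separately for events
    and censored rows; ``"pooled"`` ignores event status when choosing
    parents (the synthetic event indicator then copies the seed parent's).
    """

    k_neighbors: int = 5
    target: str | Mapping[str, int] = "majority"
    strata_mode: str = "within-event-status"
    #: a stratum with a single row cannot be interpolated; by default this
    #: is an error, but the pipeline may skip such strata (their share of
    #: synthetic rows moves to the class's other stratum) with a log entry.
    skip_singleton_strata: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.strata_mode not in ("within-event-status", "pooled"):
            raise ValueError(f"unknown strata_mode {self.strata_mode!r}")


@dataclasses.dataclass
class BalancedSet:
    """Original plus synthetic rows with full synthesis provenance.

    ``data`` carries the original columns plus ``class_label``,
    ``synthetic`` (bool), ``parent_a``/``parent_b`` (ids of the seed and
    neighbor parents) and ``weight`` (the interpolation weight w, with
    synthetic = (1-w)·parent_a + w·parent_b on every interpolated column).
    """

    data: pd.DataFrame
    feature_cols: list[str]
    n_original: int
    n_synthetic: int

    def class_sizes(self) -> pd.Series:
        return self.data["class_label"].value_counts()

    @property
    def synthetic_rows(self) -> pd.DataFrame:
        return self.data[self.data["synthetic"]]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


class SurvivalSMOTE(BaseEstimator):
    """SMOTE-style balancer for labeled survival rows (see module docs)."""

    def __init__(self, k_neighbors: int = 5,
                 target: str | Mapping[str, int] = "majority",
                 strata_mode: str = "within-event-status",
                 skip_singleton_strata: bool = False,
                 random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.target = target
        self.strata_mode = strata_mode
        self.skip_singleton_strata = skip_singleton_strata
        self.random_state = random_state

    def _config(self) -> SmoteConfig:
        cfg = SmoteConfig(self.k_neighbors, self.target, self.strata_mode,
                          self.skip_singleton_strata, self.random_state)
        cfg.validate()
        return cfg

    def fit_resample(
        self,
        data: pd.DataFrame,
        labels: Sequence[str],
        feature_cols: Sequence[str] | None = None,
    ) -> BalancedSet:
        cfg = self._config()
        data = data.reset_index(drop=True)
        labels = pd.Series(np.asarray(labels, dtype=object), name="class_label")
        if len(labels) != len(data):
            raise ValueError("labels length must match data")
        classes = labels.value_counts()
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to balance")
        if feature_cols is None:
            feature_cols = [c for c in data.columns
                            if c not in _NON_FEATURE_COLS
                            and pd.api.types.is_numeric_dtype(data[c])]
        feature_cols = list(feature_cols)
        if not feature_cols:
            raise ValueError("no feature columns for the SMOTE metric")

        if cfg.target == "majority":
            targets = {c: int(classes.max()) for c in classes.index}
        else:
            targets = {c: int(cfg.target.get(c, classes[c])) for c in classes.index}
            low = {c: t for c, t in targets.items() if t < classes[c]}
            if low:
                raise ValueError(f"target below current class size: {low}")

        rng = np.random.default_rng(cfg.seed)
        out = data.copy()
        out["class_label"] = labels
        out["synthetic"] = False
        out["parent_a"] = ""
        out["parent_b"] = ""
        out["weight"] = 0.0
        synthetic_frames = [out]
        n_syn_total = 0

        ids = (data["patient_id"].astype(str) if "patient_id" in data
               else pd.Series([str(i) for i in range(len(data))]))

        for cls in classes.index:
            need = targets[cls] - int(classes[cls])
            if need <= 0:
                continue
            cls_idx = np.flatnonzero((labels == cls).to_numpy())
            strata = self._strata(data, cls_idx, cfg)
            self._check_strata(cls, strata, cfg)
            strata = [s for s in strata if len(s) >= 2]
            if not strata:
                logger.warning("class %r has no stratum of size >= 2; skipped", cls)
                continue
            alloc = _largest_remainder(
                need, np.array([len(s) for s in strata], float))
            for stratum_idx, m in zip(strata, alloc):
                if m == 0:
                    continue
                frame = self._synthesize(
                    data, ids, stratum_idx, int(m), feature_cols, cfg, rng, cls)
                synthetic_frames.append(frame)
                n_syn_total += len(frame)

        result = pd.concat(synthetic_frames, ignore_index=True)
        return BalancedSet(result, feature_cols, len(data), n_syn_total)

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _strata(data, cls_idx, cfg) -> list[np.ndarray]:
        if cfg.strata_mode == "within-event-status" and "event" in data:
            ev = data["event"].to_numpy(int)[cls_idx]
            return [cls_idx[ev == v] for v in (1, 0) if (ev == v).any()]
        return [cls_idx]

    @staticmethod
    def _check_strata(cls, strata, cfg) -> None:
        for s in strata:
            if len(s) == 1:
                if cfg.skip_singleton_strata:
                    logger.warning(
                        "singleton stratum in class %r skipped for synthesis", cls)
                else:
                    raise ValueError(
                        f"minority stratum of size 1 in class {cls!r}: "
                        "cannot interpolate (duplication fallback is disabled)")

    @staticmethod
    def _synthesize(data, ids, stratum_idx, m, feature_cols, cfg, rng, cls):
        k = cfg.k_neighbors
        if len(stratum_idx) <= k:
            k = len(stratum_idx) - 1
            logger.warning(
                "stratum of class %r has %d rows; reducing k to %d",
                cls, len(stratum_idx), k)
        F = data.loc[stratum_idx, feature_cols].to_numpy(float)
        mu = F.mean(axis=0)
        sd = F.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Fs = (F - mu) / sd
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Fs)
        _, nbrs = nn.kneighbors(Fs)  # column 0 is the point itself

        seeds = rng.integers(len(stratum_idx), size=m)
        picks = rng.integers(1, k + 1, size=m)
        w = rng.uniform(size=m)
        rows = []
        for s_loc, pick, wi in zip(seeds, picks, w):
            n_loc = int(nbrs[s_loc, pick])
            a, b = stratum_idx[s_loc], stratum_idx[n_loc]
            row = data.loc[a].copy()  # categoricals copy from the seed parent
            for col in feature_cols:
                row[col] = (1 - wi) * data.at[a, col] + wi * data.at[b, col]
            for col in _INTERP_COLS:
                if col in data:
                    row[col] = (1 - wi) * data.at[a, col] + wi * data.at[b, col]
            if "patient_id" in data:
                row["patient_id"] = f"SMOTE-{ids[a]}-{ids[b]}-{len(rows)}"
            row["class_label"] = cls
            row["synthetic"] = True
            row["parent_a"] = ids[a]
            row["parent_b"] = ids[b]
            row["weight"] = wi
            rows.append(row)
        return pd.DataFrame(rows).reset_index(drop=True)


def smote_balance(
    rows: pd.DataFrame,
    labels: Sequence[str],
    config: SmoteConfig | None = None,
    feature_cols: Sequence[str] | None = None,
) -> BalancedSet:
    """Functional wrapper over :class:`SurvivalSMOTE`."""
    cfg = config or SmoteConfig()
    cfg.validate()
    return SurvivalSMOTE(cfg.k_neighbors, cfg.target, cfg.strata_mode,
                         cfg.skip_singleton_strata,
                         cfg.seed).fit_resample(rows, labels, feature_cols)


def _largest_remainder(total: int, sizes: np.ndarray) -> np.ndarray:
    """Apportion ``total`` proportionally to ``sizes`` (largest remainder),
    so each stratum's share of synthetic rows tracks its share of the class."""
    quota = total * sizes / sizes.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base
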