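"""Elastic-net Cox selection-frequency ranking.

The stability-selection protocol at the heart of the package: an
elastic-net penalized Cox proportional-hazards model is refit on repeated
Monte-Carlo subsamples of the cohort, once for every mixing value α on an
11-point grid from pure ridge (α=0) to pure lasso (α=1), with the penalty
weight λ chosen per fit by k-fold cross-validated partial-likelihood
deviance.  Every feature that receives a non-zero coefficient in a fit is
"selected"; features are ranked by how many of the ``n_runs × |α grid|``
models selected them.

The penalized solver for α > 0 is a coordinate-descent elastic-net Cox
path fit; the λ=0 (unpenalized) and α=0 (pure ridge) cases go through the
package's Newton–Raphson maximizer of the Breslow partial likelihood.
Throughout, λ is normalized per observation: the fitted β minimizes
``-loglik/n + λ (α‖β‖₁ + (1-α)/2 ‖β‖₂²)``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from radsurv._cox import loglik_grad_hess, newton_cox, vvh_deviance
from radsurv.cohort import Cohort

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))


class FitFailure(RuntimeError):
    """A penalized Cox fit (or its λ selection) did not produce a usable model."""


# ---------------------------------------------------------------------------
# single fits
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CoxFit:
    """Result of one (α, λ) penalized Cox fit.

    Coefficients are on the standardized-feature scale and include an
    exact 0 for any feature dropped for zero variance.
    """

    coefficients: np.ndarray
    alpha: float
    lam: float
    converged: bool
    n_iter: int
    dropped: tuple[str, ...] = ()

    def selected(self, tol: float = 1e-8) -> np.ndarray:
        return np.abs(self.coefficients) > tol


def _as_xy(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns to unit variance; returns (Xs, keep-mask)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, keep


def fit_penalized_cox(
    X,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float,
    lam: float,
    *,
    standardize: bool = True,
    tol: float = 1e-9,
    max_iter: int = 100_000,
) -> CoxFit:
    """Fit one elastic-net penalized Cox model at a fixed (α, λ).

    Minimizes ``-loglik(β)/n + λ (α‖β‖₁ + (1-α)/2 ‖β‖₂²)`` with Breslow
    tie handling.  Zero-variance features are dropped with a log entry and
    reported with coefficient exactly 0.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    Xa, names = _as_xy(X)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n, p = Xa.shape
    if int(event.sum()) < 2:
        raise ValueError("at least 2 events are required")
    if standardize:
        Xw, keep = _standardize(Xa)
    else:
        sd = Xa.std(axis=0, ddof=0)
        keep = sd > 0
        Xw = Xa[:, keep]
    dropped = tuple(np.asarray(names, dtype=object)[~keep])
    if dropped:
        logger.info("dropping %d zero-variance features: %s", len(dropped), dropped[:5])
    if not keep.any():
        raise FitFailure("no feature with non-zero variance")

    beta = np.zeros(p)
    if lam == 0.0:
        res = newton_cox(Xw, time, event, l2=0.0, tol=tol)
        beta[keep] = res.beta
        return CoxFit(beta, alpha, lam, res.converged, res.n_iter, dropped)
    if alpha == 0.0:
        res = newton_cox(Xw, time, event, l2=n * lam, tol=tol)
        beta[keep] = res.beta
        return CoxFit(beta, alpha, lam, res.converged, res.n_iter, dropped)

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=alpha, alphas=[lam], normalize=False,
        fit_baseline_model=False, max_iter=max_iter, tol=1e-7,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xw, y)
    except (ArithmeticError, ValueError) as exc:  # numerical failure
        raise FitFailure(f"coordinate descent failed at alpha={alpha}, lam={lam}: {exc}")
    beta[keep] = model.coef_[:, 0]
    return CoxFit(beta, alpha, lam, True, int(getattr(model, "n_iter_", 0) or 0), dropped)


# ---------------------------------------------------------------------------
# λ path and cross-validation
# ---------------------------------------------------------------------------

def lambda_path(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float,
    *,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.05,
) -> np.ndarray:
    """Geometric λ path from λ_max (all-zero lasso solution) downwards.

    λ_max = max_j |∂loglik/∂β_j at β=0| / (n · max(α, 0.01)); the α floor
    keeps the path finite for the ridge end of the grid.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    _, g, _ = loglik_grad_hess(np.zeros(X.shape[1]), X, time, event, hess=False)
    lam_max = float(np.max(np.abs(g))) / (n * max(alpha, 0.01))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _ridge_path_fits(Xtr, ttr, etr, path):
    """Warm-started Newton ridge fits along a descending λ path."""
    betas = np.empty((Xtr.shape[1], len(path)))
    b0 = None
    for k, lam in enumerate(path):
        res = newton_cox(Xtr, ttr, etr, l2=len(ttr) * lam, beta0=b0, tol=1e-7)
        if not res.converged:
            raise FitFailure(f"ridge Newton did not converge at lam={lam}")
        betas[:, k] = res.beta
        b0 = res.beta
    return betas


def cv_select_lambda(
    X,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float,
    cv_folds: int = 10,
    seed: int = 0,
    *,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.05,
    path: np.ndarray | None = None,
    standardize: bool = True,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    return_curve: bool = False,
):
    """Select λ minimizing mean k-fold cross-validated partial-likelihood
    deviance (Verweij–Van Houwelingen form) over a geometric λ path.

    Folds are stratified by event status so every fold retains events; an
    explicit list of (train, test) index pairs overrides the stratified
    split.  Ties in the deviance curve resolve to the larger (more
    parsimonious) λ.
    """
    Xa, _ = _as_xy(X)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if standardize:
        Xs, keep = _standardize(Xa)
    else:
        Xs = Xa
    n = Xs.shape[0]
    if not 2 <= cv_folds <= n:
        raise ValueError(f"cv_folds must be in [2, n]={n}, got {cv_folds}")
    if int(event.sum()) < cv_folds:
        raise ValueError("need at least one event per fold (events < cv_folds)")
    if path is None:
        path = lambda_path(Xs, time, event, alpha,
                           n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    path = np.asarray(path, float)

    if folds is None:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=int(seed) % (2**31))
        with warnings.catch_warnings():
            # folds with no censored rows are fine; only events must spread
            warnings.simplefilter("ignore", UserWarning)
            folds = list(skf.split(Xs, event))
    dev = np.zeros((len(folds), len(path)))
    ok = np.ones((len(folds), len(path)), dtype=bool)
    y_all = Surv.from_arrays(event=event.astype(bool), time=time)
    for f, (tr, _te) in enumerate(folds):
        Xtr, ttr, etr = Xs[tr], time[tr], event[tr]
        try:
            if alpha == 0.0:
                betas = _ridge_path_fits(Xtr, ttr, etr, path)
            else:
                model = CoxnetSurvivalAnalysis(
                    l1_ratio=alpha, alphas=path, normalize=False,
                    fit_baseline_model=False, tol=1e-7,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(Xtr, y_all[tr])
                betas = model.coef_
                if betas.shape[1] < len(path):  # path terminated early
                    ok[f, betas.shape[1]:] = False
        except (ArithmeticError, ValueError, FitFailure) as exc:
            logger.warning("CV fold %d failed entirely: %s", f, exc)
            ok[f, :] = False
            continue
        for k in range(min(betas.shape[1], len(path))):
            dev[f, k] = vvh_deviance(betas[:, k], Xs, time, event, tr)

    valid = ok.all(axis=0)
    if not valid.any():
        raise FitFailure("cross-validation failed for every lambda on the path")
    mean_dev = np.where(valid, dev.mean(axis=0), np.inf)
    best = mean_dev.min()
    # ties (within numerical noise) resolve to the larger λ = first index
    idx = int(np.flatnonzero(mean_dev <= best + 1e-10)[0])
    lam = float(path[idx])
    if return_curve:
        return lam, path, mean_dev
    return lam


# ---------------------------------------------------------------------------
# frequency table and ranking
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FrequencyTable:
    """Per-feature selection counts over the run × α grid.

    ``table`` has one row per feature with columns ``feature``,
    ``category``, ``count``, ``exposure`` (models in which the feature
    entered a successful fit), ``failures`` (models lost to fit failures
    while the feature was exposed), ``total_models`` and the tie-aware
    competition ``rank`` (equal counts share the better rank).
    """

    table: pd.DataFrame
    total_models: int

    def __post_init__(self) -> None:
        t = self.table
        if (t["count"] > t["exposure"]).any():
            raise ValueError("count cannot exceed exposure")
        if ((t["exposure"] + t["failures"]) > self.total_models).any():
            raise ValueError("exposure + failures cannot exceed total_models")

    def top(self, k: int) -> pd.DataFrame:
        """Top-k rows (all rows if k exceeds the feature count)."""
        if k < 1:
            raise ValueError("top_k must be >= 1")
        return self.table.head(min(k, len(self.table))).reset_index(drop=True)

    def top_tie_group(self) -> list[str]:
        """Features sharing the maximal selection count (rank-1 tie group)."""
        best = self.table["count"].max()
        return list(self.table.loc[self.table["count"] == best, "feature"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def from_counts(
        features: Sequence[str],
        counts: np.ndarray,
        exposure: np.ndarray,
        failures: np.ndarray,
        total_models: int,
        categories: dict[str, str] | None = None,
    ) -> "FrequencyTable":
        df = pd.DataFrame({
            "feature": list(features),
            "category": [
                (categories or {}).get(f, "") for f in features
            ],
            "count": counts.astype(int),
            "exposure": exposure.astype(int),
            "failures": failures.astype(int),
        })
        df["total_models"] = int(total_models)
        # competition ranking: rank = 1 + number of strictly larger counts
        df = df.sort_values(["count", "feature"], ascending=[False, True],
                            kind="stable").reset_index(drop=True)
        counts_sorted = df["count"].to_numpy()
        df["rank"] = [int((counts_sorted > c).sum()) + 1 for c in counts_sorted]
        cols = ["rank", "feature", "category", "count", "exposure",
                "failures", "total_models"]
        return FrequencyTable(df[cols], int(total_models))


def rank_features(freq: FrequencyTable, top_k: int) -> pd.DataFrame:
    """Descending-count ranking with tie-aware competition ranks.

    Ties are broken for display only, alphabetically by feature name;
    tie-group membership is recoverable from the shared ``rank`` value.
    """
    return freq.top(top_k)


# ---------------------------------------------------------------------------
# the Monte-Carlo × α-grid protocol
# ---------------------------------------------------------------------------

class ElasticNetFrequencyRanker(BaseEstimator):
    """Stability-selection feature ranker for right-censored outcomes.

    For each of ``n_runs`` Monte-Carlo subsamples (fraction
    ``subsample_fraction`` drawn without replacement) and each mixing value
    of ``alpha_grid``, λ is chosen by ``cv_folds``-fold cross-validated
    partial-likelihood deviance and the model refit on the whole subsample;
    features with ``|β| > nonzero_tol`` are counted as selected.

    Because a ridge fit (α=0) is dense — every coefficient is non-zero
    almost surely — the α=0 column counts every exposed feature as
    selected; ``ridge_dense=False`` forces the explicit CV+fit instead.

    Attributes
    ----------
    counts_, exposure_, failures_ : ndarray of int, shape (n_features,)
    total_models_ : int, ``n_runs * len(alpha_grid)``
    frequency_table_ : FrequencyTable
    feature_names_in_ : list of str
    """

    def __init__(
        self,
        alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
        n_runs: int = 100,
        cv_folds: int = 10,
        subsample_fraction: float = 0.8,
        n_lambda: int = 30,
        lambda_min_ratio: float = 0.05,
        standardize: bool = True,
        nonzero_tol: float = 1e-8,
        ridge_dense: bool = True,
        top_k: int = 16,
        random_state: int = 0,
    ):
        self.alpha_grid = alpha_grid
        self.n_runs = n_runs
        self.cv_folds = cv_folds
        self.subsample_fraction = subsample_fraction
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.nonzero_tol = nonzero_tol
        self.ridge_dense = ridge_dense
        self.top_k = top_k
        self.random_state = random_state

    # -- validation ------------------------------------------------------
    def _validate_config(self, n: int) -> list[float]:
        grid = [float(a) for a in self.alpha_grid]
        if len(grid) != len(set(grid)):
            raise ValueError("alpha_grid values must be unique")
        if any(not 0 <= a <= 1 for a in grid):
            raise ValueError("alpha_grid values must lie in [0, 1]")
        if not 2 <= self.cv_folds <= n:
            raise ValueError(f"cv_folds must be in [2, {n}]")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        return grid

    @staticmethod
    def _split_y(y) -> tuple[np.ndarray, np.ndarray]:
        """Accept a sksurv structured array, a (time, event) tuple, or a
        DataFrame with time/event columns."""
        if isinstance(y, tuple) and len(y) == 2:
            return np.asarray(y[0], float), np.asarray(y[1], int)
        if isinstance(y, pd.DataFrame):
            return y["time"].to_numpy(float), y["event"].to_numpy(int)
        arr = np.asarray(y)
        if arr.dtype.names:  # structured survival array
            names = list(arr.dtype.names)
            ev_field = next((f for f in names if arr.dtype[f] == np.bool_),
                            names[0])
            t_field = next(f for f in names if f != ev_field)
            return arr[t_field].astype(float), arr[ev_field].astype(int)
        raise TypeError("y must be a structured survival array, (time, event) "
                        "tuple, or a DataFrame with time/event columns")

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y, categories: dict[str, str] | None = None):
        Xa, names = _as_xy(X)
        time, event = self._split_y(y)
        n, p = Xa.shape
        grid = self._validate_config(n)
        m = max(2, int(round(self.subsample_fraction * n)))

        counts = np.zeros(p, dtype=int)
        exposure = np.zeros(p, dtype=int)
        failures = np.zeros(p, dtype=int)

        root = np.random.SeedSequence(self.random_state)
        run_seeds = root.spawn(self.n_runs)
        for r, ss in enumerate(run_seeds):
            rng = np.random.default_rng(ss)
            idx = self._draw_subsample(rng, n, m, event)
            Xsub, tsub, esub = Xa[idx], time[idx], event[idx]
            if self.standardize:
                Xs, keep = _standardize(Xsub)
            else:
                keep = Xsub.std(axis=0, ddof=0) > 0
                Xs = Xsub[:, keep]
            kept_idx = np.flatnonzero(keep)
            for alpha in grid:
                cv_seed = int(rng.integers(2**31))
                if alpha == 0.0 and self.ridge_dense:
                    counts[kept_idx] += 1
                    exposure[kept_idx] += 1
                    continue
                try:
                    lam = cv_select_lambda(
                        Xs, tsub, esub, alpha, self.cv_folds, cv_seed,
                        n_lambda=self.n_lambda,
                        lambda_min_ratio=self.lambda_min_ratio,
                        standardize=False,
                    )
                    fit = fit_penalized_cox(
                        Xs, tsub, esub, alpha, lam, standardize=False)
                    if not fit.converged:
                        raise FitFailure("final fit did not converge")
                except (FitFailure, ValueError) as exc:
                    logger.warning("run %d alpha %.1f excluded: %s", r, alpha, exc)
                    failures[kept_idx] += 1
                    continue
                sel = np.abs(fit.coefficients) > self.nonzero_tol
                counts[kept_idx[sel]] += 1
                exposure[kept_idx] += 1

        self.feature_names_in_ = names
        self.counts_ = counts
        self.exposure_ = exposure
        self.failures_ = failures
        self.total_models_ = self.n_runs * len(grid)
        self.frequency_table_ = FrequencyTable.from_counts(
            names, counts, exposure, failures, self.total_models_, categories)
        return self

    @staticmethod
    def _draw_subsample(rng, n, m, event, max_tries: int = 100) -> np.ndarray:
        """Draw m of n rows without replacement, requiring >= 2 events."""
        for _ in range(max_tries):
            idx = rng.choice(n, size=m, replace=False)
            if event[idx].sum() >= 2:
                return np.sort(idx)
        raise FitFailure("could not draw a subsample with >= 2 events")

    # -- selector interface ---------------------------------------------
    def get_support(self, indices: bool = False):
        top = set(self.frequency_table_.top(self.top_k)["feature"])
        mask = np.array([f in top for f in self.feature_names_in_])
        return np.flatnonzero(mask) if indices else mask

    def transform(self, X):
        mask = self.get_support()
        if isinstance(X, pd.DataFrame):
            return X.loc[:, mask]
        return np.asarray(X)[:, mask]

    def fit_transform(self, X, y, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


@dataclasses.dataclass
class RankingConfig:
    """Configuration of the frequency-ranking protocol (see
    :class:`ElasticNetFrequencyRanker` for semantics)."""

    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    n_runs: int = 100
    cv_folds: int = 10
    subsample_fraction: float = 0.8
    n_lambda: int = 30
    lambda_min_ratio: float = 0.05
    standardize: bool = True
    nonzero_tol: float = 1e-8
    ridge_dense: bool = True
    top_k: int = 16
    seed: int = 0

    def to_estimator(self) -> ElasticNetFrequencyRanker:
        return ElasticNetFrequencyRanker(
            alpha_grid=tuple(self.alpha_grid),
            n_runs=self.n_runs,
            cv_folds=self.cv_folds,
            subsample_fraction=self.subsample_fraction,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            standardize=self.standardize,
            nonzero_tol=self.nonzero_tol,
            ridge_dense=self.ridge_dense,
            top_k=self.top_k,
            random_state=self.seed,
        )


def run_frequency_ranking(cohort: Cohort, config: RankingConfig) -> FrequencyTable:
    """Run the full Monte-Carlo × α-grid protocol on a cohort's radiomic
    features (clinical covariates do not enter the penalized model)."""
    est = config.to_estimator()
    est.fit(cohort.features, (cohort.time, cohort.event),
            categories=dict(cohort.feature_categories))
    return est.frequency_table_
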