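"""Presence-background suitability modelling and reciprocal projection.

The maximum-entropy presence-background model is fitted in its
penalized-GLM form: an L1-regularized logistic regression of presences
against background cells on linear + quadratic features of the
standardized climate variables, with suitability read off the logistic
output scale (delta in [0, 1]).  Cross-validation splits the presences
into k folds (default 5) that share the background; per-fold AUC scores
the model's discrimination, and the retained fold models support an
ensemble version of the increased-suitability metric.

Contrasting the reciprocal projections on the introduced region yields
the increased-introduced-suitability percentage

    100 * sum_ij(delta_introduced_model - delta_native_model)
        / sum_ij(delta_introduced_model),

the raster-difference summary of how much more of the introduced region
the introduced-range model deems suitable than the native-range model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .grids import ClimateGrid
from .occurrences import OccurrenceSet

__all__ = [
    "MaxEntSuitability",
    "SuitabilityMap",
    "EnsembleResult",
    "fit_suitability",
    "project",
    "increased_suitability",
    "increased_suitability_ensemble",
]

LAMBDA_GRID = (0.01, 0.1, 1.0)


@dataclass
class _FoldModel:
    """One cross-validation fold's coefficient set, sharing the parent's
    standardization and feature expansion."""

    parent: "MaxEntSuitability"
    coef: np.ndarray
    intercept: float

    def predict_suitability(self, X) -> np.ndarray:
        phi = self.parent._features(X)
        return expit(phi @ self.coef + self.intercept)


class MaxEntSuitability(BaseEstimator):
    """L1-penalized logistic presence-background suitability model.

    Parameters
    ----------
    l1_penalty : float or None
        Regularization strength lambda (inverse of sklearn's ``C``).
        ``None`` selects lambda from ``{0.01, 0.1, 1}`` by the
        one-standard-error rule on cross-validated AUC (the strongest
        penalty within one SE of the best mean).
    folds : int
        Number of presence folds for cross-validation.
    random_state : int or None
        Seed for fold assignment.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : final model on linear + quadratic features
    lambda_ : the regularization actually used
    cv_auc_ : per-fold AUC of presences vs shared background
    fold_models_ : the k fold models (for ensemble projections)
    train_min_, train_max_ : per-variable training bounds (novelty flags)
    """

    def __init__(
        self,
        l1_penalty: Optional[float] = None,
        folds: int = 5,
        random_state: Optional[int] = None,
    ):
        self.l1_penalty = l1_penalty
        self.folds = folds
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _as_frame(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"v{i}" for i in range(X.shape[1])]
        return X.astype(float)

    def _features(self, X) -> np.ndarray:
        X = self._as_frame(X)
        missing = [v for v in self.variables_ if v not in X.columns]
        if missing:
            raise ValueError(f"missing variable(s): {missing}")
        Z = (X[self.variables_].to_numpy() - self.mean_) / self.scale_
        return np.hstack([Z, Z**2])

    def _fit_glm(self, phi: np.ndarray, y: np.ndarray, lam: float):
        if lam <= 0:
            raise ValueError(
                "l1_penalty must be positive; with lambda = 0 complete "
                "separation is possible -- use lambda > 0"
            )
        clf = LogisticRegression(
            l1_ratio=1.0,  # pure L1 penalty
            C=1.0 / lam,
            solver="liblinear",
            max_iter=2000,
            random_state=self.random_state,
        )
        clf.fit(phi, y)
        return clf.coef_[0].copy(), float(clf.intercept_[0])

    def fit(self, X, y) -> "MaxEntSuitability":
        X = self._as_frame(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("y must contain presences (1) and background (0)")
        pres_idx = np.flatnonzero(y == 1)
        if len(pres_idx) < self.folds:
            raise ValueError(
                f"fewer presences ({len(pres_idx)}) than folds ({self.folds})"
            )
        self.variables_ = list(X.columns)
        vals = X.to_numpy()
        self.mean_ = vals.mean(axis=0)
        scale = vals.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        self.train_min_ = vals.min(axis=0)
        self.train_max_ = vals.max(axis=0)
        phi = self._features(X)
        bg_idx = np.flatnonzero(y == 0)

        kf = KFold(n_splits=self.folds, shuffle=True, random_state=self.random_state)
        splits = list(kf.split(pres_idx))

        def cv_auc(lam: float):
            aucs, models = [], []
            for train, test in splits:
                rows = np.concatenate([pres_idx[train], bg_idx])
                coef, icpt = self._fit_glm(phi[rows], y[rows], lam)
                scores = phi @ coef + icpt
                eval_rows = np.concatenate([pres_idx[test], bg_idx])
                aucs.append(roc_auc_score(y[eval_rows], scores[eval_rows]))
                models.append((coef, icpt))
            return np.asarray(aucs), models

        if self.l1_penalty is None:
            # one-SE rule: the strongest penalty whose mean CV AUC is
            # within one standard error of the best -- robust when the
            # model is transferred beyond its training region
            trials = {lam: cv_auc(lam) for lam in LAMBDA_GRID}
            means = {lam: a.mean() for lam, (a, _) in trials.items()}
            best_lam = max(means, key=means.get)
            best_aucs = trials[best_lam][0]
            cutoff = means[best_lam] - best_aucs.std(ddof=1) / np.sqrt(len(best_aucs))
            lam = max(l for l in LAMBDA_GRID if means[l] >= cutoff)
            aucs, models = trials[lam]
        else:
            lam = float(self.l1_penalty)
            aucs, models = cv_auc(lam)

        self.lambda_ = lam
        self.cv_auc_ = aucs
        self.fold_models_ = [
            _FoldModel(self, coef, icpt) for coef, icpt in models
        ]
        self.coef_, self.intercept_ = self._fit_glm(phi, y, lam)
        return self

    # ------------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._features(X) @ self.coef_ + self.intercept_

    def predict_suitability(self, X) -> np.ndarray:
        """Suitability delta in [0, 1] (logistic output)."""
        return expit(self.decision_function(X))

    def novelty(self, X) -> np.ndarray:
        """True where any variable falls outside the training min/max."""
        check_is_fitted(self, "coef_")
        X = self._as_frame(X)[self.variables_].to_numpy()
        return ((X < self.train_min_) | (X > self.train_max_)).any(axis=1)


@dataclass
class SuitabilityMap:
    """Per-cell suitability delta projected onto a region's grid."""

    delta: np.ndarray
    source_model: str
    projection_region: str
    novel: np.ndarray  # cells outside the model's training climate

    def __post_init__(self) -> None:
        finite = self.delta[np.isfinite(self.delta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def n_novel(self) -> int:
        return int(np.asarray(self.novel, dtype=bool).sum())


@dataclass
class EnsembleResult:
    """Increased-suitability metric over all fold-model pairs."""

    mean: float
    sem: float
    values: np.ndarray


def fit_suitability(
    occ: OccurrenceSet,
    grid: ClimateGrid,
    n_background: int = 10_000,
    l1_penalty: Optional[float] = None,
    folds: int = 5,
    seed: int = 0,
) -> MaxEntSuitability:
    """Fit the presence-background model for one range.

    Background points are a seeded random sample of the region's cells
    (capped at the region size); presences come from the annotated
    occurrence set.
    """
    if occ.env is None:
        raise ValueError("occurrence set is not environmentally annotated")
    if len(occ) < 10:
        raise ValueError("need at least 10 presences to fit a suitability model")
    env = grid.env_table()
    rng = np.random.default_rng(seed)
    n_bg = min(n_background, len(env))
    bg = env.iloc[rng.choice(len(env), size=n_bg, replace=False)]
    X = pd.concat([occ.env[env.columns], bg], ignore_index=True)
    y = np.concatenate([np.ones(len(occ), dtype=int), np.zeros(n_bg, dtype=int)])
    model = MaxEntSuitability(l1_penalty=l1_penalty, folds=folds, random_state=seed)
    model.fit(X, y)
    model.training_range_ = occ.ranges[0] if occ.ranges else grid.region
    return model


def _project_values(predict, novelty, grid: ClimateGrid):
    env = grid.env_table(dropna=False)
    valid = env.notna().all(axis=1).to_numpy()
    delta = np.full(len(env), np.nan)
    novel = np.zeros(len(env), dtype=bool)
    if valid.any():
        delta[valid] = predict(env.loc[valid])
        novel[valid] = novelty(env.loc[valid])
    shape = grid.shape
    return delta.reshape(shape), novel.reshape(shape)


def project(model: MaxEntSuitability, grid: ClimateGrid) -> SuitabilityMap:
    """Project a fitted model onto a region's climate grid.

    Standardization constants are frozen from the training region (the
    transfer convention); cells whose climate falls outside the training
    min/max of any variable are flagged as novel (MESS-like indicator).
    """
    check_is_fitted(model, "coef_")
    missing = [v for v in model.variables_ if v not in grid.layers]
    if missing:
        raise ValueError(f"projection grid lacks model variable(s): {missing}")
    delta, novel = _project_values(model.predict_suitability, model.novelty, grid)
    return SuitabilityMap(
        delta=delta,
        source_model=getattr(model, "training_range_", "unknown"),
        projection_region=grid.region,
        novel=novel,
    )


def increased_suitability(
    map_introduced_model: SuitabilityMap,
    map_native_model: SuitabilityMap,
) -> float:
    """Increased-introduced-suitability percentage on a shared region.

    ``100 * sum(delta_introduced - delta_native) / sum(delta_introduced)``
    over cells valid in both maps.  Positive values mean the
    introduced-range model finds the region more suitable than the
    native-range model does.
    """
    dE = np.asarray(map_introduced_model.delta, dtype=float)
    dN = np.asarray(map_native_model.delta, dtype=float)
    if dE.shape != dN.shape:
        raise ValueError("suitability maps are not on the same grid")
    if map_introduced_model.projection_region != map_native_model.projection_region:
        raise ValueError("suitability maps cover different regions")
    valid = np.isfinite(dE) & np.isfinite(dN)
    total = dE[valid].sum()
    if total <= 0:
        raise ValueError("degenerate introduced-range model: total suitability is 0")
    return float(100.0 * (dE[valid] - dN[valid]).sum() / total)


def increased_suitability_ensemble(
    model_introduced: MaxEntSuitability,
    model_native: MaxEntSuitability,
    grid: ClimateGrid,
) -> EnsembleResult:
    """The metric over all fold-model pairs (k x k), with mean and SEM."""
    folds_i = getattr(model_introduced, "fold_models_", [])
    folds_n = getattr(model_native, "fold_models_", [])
    if len(folds_i) < 2 or len(folds_n) < 2:
        raise ValueError("need at least 2 folds per model for an ensemble")
    env = grid.env_table()
    values = []
    deltas_i = [fm.predict_suitability(env) for fm in folds_i]
    deltas_n = [fm.predict_suitability(env) for fm in folds_n]
    for dE in deltas_i:
        total = dE.sum()
        if total <= 0:
            raise ValueError("degenerate introduced-range fold model")
        for dN in deltas_n:
            values.append(100.0 * (dE - dN).sum() / total)
    values = np.asarray(values)
    sem = float(values.std(ddof=1) / np.sqrt(len(values)))
    return EnsembleResult(mean=float(values.mean()), sem=sem, values=values)
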