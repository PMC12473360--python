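"""Stage-wise dataset splitting and the three biomass regression models.

Three estimators are compared per growth stage and feature set: a univariate
least-squares "simple" regression on the single best-screened feature,
multiple linear regression (ordinary least squares), and a random forest
whose hyperparameters are tuned by TPE search over 10-fold cross-validated
R2.  Forest inputs are z-score standardised with statistics fitted on the
training partition only.  Performance is reported as R2 and RMSE (g/m2) on
both partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from . import tuning
from .tuning import Categorical, FloatUniform, IntUniform

__all__ = [
    "StageDataset",
    "ModelSpec",
    "FitResult",
    "split_stagewise",
    "fit_simple_regression",
    "fit_mlr",
    "fit_rf_tuned",
    "evaluate",
    "DEFAULT_RF_SPACE",
]

logger = logging.getLogger(__name__)

STAGES = ("pre_heading", "post_heading", "all_stage")

#: default random-forest search ranges
DEFAULT_RF_SPACE: Dict[str, Any] = {
    "n_estimators": IntUniform(50, 500),
    "max_depth": IntUniform(3, 30),
    "min_samples_split": IntUniform(2, 10),
    "min_samples_leaf": IntUniform(1, 10),
    "max_features_kind": Categorical(("sqrt", "log2", "fraction")),
    "max_features_fraction": FloatUniform(0.3, 1.0),
}


@dataclass
class StageDataset:
    """Train/test feature matrices and AGB vectors for one stage."""

    stage: str
    X_train: pd.DataFrame
    X_test: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray

    @property
    def feature_names(self) -> List[str]:
        return list(self.X_train.columns)

    @property
    def n_train(self) -> int:
        return len(self.X_train)

    @property
    def n_test(self) -> int:
        return len(self.X_test)


@dataclass
class ModelSpec:
    """Configuration of the tuned random-forest search."""

    kind: str = "rf"
    space: Dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_RF_SPACE))
    n_trials: int = 100
    cv_folds: int = 10
    seed: int = 0


@dataclass
class FitResult:
    """A fitted model plus its hyperparameters and partition metrics."""

    model: Any
    kind: str
    params: Dict[str, Any]
    metrics: Dict[str, Tuple[float, float]]  # partition -> (R2, RMSE)
    coefficients: Optional[np.ndarray] = None
    intercept: Optional[float] = None
    scaler: Optional[StandardScaler] = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        if self.kind in ("simple", "mlr"):
            return X @ self.coefficients + self.intercept
        return self.model.predict(X)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_stagewise(
    samples_by_stage: Mapping[str, Tuple[pd.DataFrame, Sequence[float]]],
    train_fraction: float = 0.75,
    seed: int = 0,
) -> Dict[str, StageDataset]:
    """Random per-stage split; the all-stage sets are unions of the stage splits.

    ``samples_by_stage`` maps ``pre_heading``/``post_heading`` to a
    ``(features, agb)`` pair.  The train size is round-half-up of
    ``train_fraction * n`` (468 -> 351/117, 234 -> 176/58), membership is
    reproducible under ``seed``, and no sample lands in both partitions.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, StageDataset] = {}
    parts: Dict[str, List] = {"X_train": [], "X_test": [], "y_train": [], "y_test": []}
    for stage in ("pre_heading", "post_heading"):
        if stage not in samples_by_stage:
            raise ValueError(f"missing stage {stage!r}")
        X, y = samples_by_stage[stage]
        y = np.asarray(y, dtype=float)
        n = len(X)
        if n != y.size:
            raise ValueError(f"stage {stage!r}: feature rows and agb length differ")
        if n < 4:
            raise ValueError(f"stage {stage!r} has fewer than 4 samples")
        n_train = _round_half_up(train_fraction * n)
        perm = rng.permutation(n)
        tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        ds = StageDataset(
            stage=stage,
            X_train=X.iloc[tr],
            X_test=X.iloc[te],
            y_train=y[tr],
            y_test=y[te],
        )
        out[stage] = ds
        parts["X_train"].append(ds.X_train)
        parts["X_test"].append(ds.X_test)
        parts["y_train"].append(ds.y_train)
        parts["y_test"].append(ds.y_test)
    out["all_stage"] = StageDataset(
        stage="all_stage",
        X_train=pd.concat(parts["X_train"]),
        X_test=pd.concat(parts["X_test"]),
        y_train=np.concatenate(parts["y_train"]),
        y_test=np.concatenate(parts["y_test"]),
    )
    return out


def evaluate(y_true: Sequence[float], y_pred: Sequence[float]) -> Tuple[float, float]:
    """Coefficient of determination and root-mean-square error.

    ``R2 = 1 - SSres/SStot`` (may be negative on held-out data);
    ``RMSE = sqrt(mean((y_hat - y)^2))``.  A constant ``y_true`` makes R2
    undefined (NaN sentinel); RMSE is still returned.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length nonempty vectors")
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0.0:
        return float("nan"), rmse
    ssres = float(np.sum((y_pred - y_true) ** 2))
    return 1.0 - ssres / sstot, rmse


def _linear_fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: Optional[np.ndarray],
    y_test: Optional[np.ndarray],
    kind: str,
) -> FitResult:
    n, p = X_train.shape
    design = np.column_stack([X_train, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(design, y_train, rcond=None)
    if rank < design.shape[1]:
        logger.warning("rank-deficient design (rank %d < %d); minimum-norm solution", rank, design.shape[1])
    beta, a0 = coef[:-1], float(coef[-1])
    metrics = {"train": evaluate(y_train, X_train @ beta + a0)}
    if X_test is not None and len(X_test):
        metrics["test"] = evaluate(y_test, X_test @ beta + a0)
    return FitResult(
        model=None, kind=kind, params={}, metrics=metrics,
        coefficients=beta, intercept=a0,
    )


def fit_simple_regression(
    feature: Sequence[float],
    agb: Sequence[float],
    feature_test: Optional[Sequence[float]] = None,
    agb_test: Optional[Sequence[float]] = None,
    quadratic: bool = False,
) -> FitResult:
    """Univariate least-squares regression of AGB on one screened feature.

    With ``quadratic=True`` a second-order term is added; the default is the
    plain straight-line fit.
    """
    x = np.asarray(feature, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance feature")
    cols = [x, x**2] if quadratic else [x]
    X = np.column_stack(cols)
    Xt = yt = None
    if feature_test is not None:
        ft = np.asarray(feature_test, dtype=float)
        Xt = np.column_stack([ft, ft**2] if quadratic else [ft])
        yt = np.asarray(agb_test, dtype=float)
    return _linear_fit(X, np.asarray(agb, dtype=float), Xt, yt, kind="simple")


def fit_mlr(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    X_test=None,
    y_test=None,
) -> FitResult:
    """Multiple linear regression by ordinary least squares."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] <= Xa.shape[1]:
        raise ValueError("need n > p for multiple linear regression")
    Xt = np.asarray(X_test, dtype=float) if X_test is not None else None
    yt = np.asarray(y_test, dtype=float) if y_test is not None else None
    return _linear_fit(Xa, ya, Xt, yt, kind="mlr")


def _rf_from_params(params: Dict[str, Any], seed: int) -> RandomForestRegressor:
    if params["max_features_kind"] == "fraction":
        max_features = float(params["max_features_fraction"])
    else:
        max_features = params["max_features_kind"]
    return RandomForestRegressor(
        n_estimators=int(params["n_estimators"]),
        max_depth=int(params["max_depth"]),
        min_samples_split=int(params["min_samples_split"]),
        min_samples_leaf=int(params["min_samples_leaf"]),
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )


def fit_rf_tuned(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    spec: ModelSpec,
    X_test=None,
    y_test=None,
) -> FitResult:
    """TPE-tuned random forest with k-fold cross-validated R2 as objective.

    Inputs are z-score standardised (statistics from the training partition);
    the best configuration is refit on the full training partition.  The
    whole search is deterministic under ``spec.seed``.
    """
    if not spec.space:
        raise ValueError("empty hyperparameter search space")
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(Xa) < spec.cv_folds:
        raise ValueError("need at least cv_folds training samples")
    scaler = StandardScaler().fit(Xa)
    Xs = scaler.transform(Xa)
    folds = list(
        KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed).split(Xs)
    )

    def objective(params: Dict[str, Any]) -> float:
        scores = []
        for tr, va in folds:
            rf = _rf_from_params(params, seed=spec.seed)
            rf.fit(Xs[tr], ya[tr])
            r2, _ = evaluate(ya[va], rf.predict(Xs[va]))
            scores.append(r2)
        return float(np.mean(scores))

    best_params, best_cv, history = tuning.optimize(
        objective, spec.space, n_trials=spec.n_trials, seed=spec.seed
    )
    model = _rf_from_params(best_params, seed=spec.seed)
    model.fit(Xs, ya)
    metrics = {"train": evaluate(ya, model.predict(Xs))}
    if X_test is not None and len(np.asarray(X_test)):
        Xts = scaler.transform(np.asarray(X_test, dtype=float))
        metrics["test"] = evaluate(np.asarray(y_test, dtype=float), model.predict(Xts))
    params = dict(best_params)
    params["cv_r2"] = best_cv
    return FitResult(
        model=model, kind="rf", params=params, metrics=metrics, scaler=scaler
    )
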