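"""Brain-age predictors over ROI feature tables.

A predictor maps (features, sex) -> estimated age in years.  The default
architecture is the cascade feed-forward network (:mod:`brainpad.cascade`),
but the downstream normative machinery is predictor-agnostic, so any backend
honoring the fit/predict contract can be substituted — a ridge linear model
and gradient-boosted trees ship as alternatives, and a mean-age dummy is
available for degenerate-baseline checks.

Features are standardized per column (sex included, as a standardized binary
input) with the statistics learned on the training set only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import Ridge, RidgeCV

from .cascade import CascadeNetRegressor
from .errors import ComputationError, SchemaError, ValidationError
from .synthetic import FeatureMatrix

__all__ = [
    "BrainAgePredictor",
    "CVReport",
    "train_predictor",
    "predict_age",
    "crossvalidate_10fold",
    "performance_metrics",
    "make_backend",
]

_MIN_TRAIN_N = 50


def make_backend(name: str, hyperparams: dict | None = None, seed: int = 0):
    """Instantiate a regression backend by name.

    Known names: ``cascade`` (default architecture), ``ridge``, ``gbt``,
    ``constant``.  ``hyperparams`` are passed through to the constructor.
    """
    hp = dict(hyperparams or {})
    if name == "cascade":
        hp.setdefault("seed", seed)
        return CascadeNetRegressor(**hp)
    if name == "ridge":
        alphas = hp.pop("alphas", np.logspace(-3, 4, 15))
        if "alpha" in hp:
            return Ridge(**hp)
        return RidgeCV(alphas=alphas, **hp)
    if name == "gbt":
        hp.setdefault("random_state", seed)
        hp.setdefault("max_iter", 200)
        return HistGradientBoostingRegressor(**hp)
    if name == "constant":
        return DummyRegressor(strategy="mean")
    raise ValidationError(f"unknown backend '{name}' "
                          "(expected cascade, ridge, gbt or constant)")


@dataclass
class BrainAgePredictor:
    """A fitted brain-age regressor plus its input contract."""

    modality: str
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    backend: object
    backend_name: str
    training_metadata: dict = field(default_factory=dict)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.scale + self.center


def _design_matrix(features, sex) -> tuple[np.ndarray, list[str], pd.Index]:
    """Assemble the raw design (features + sex column) with names and ids."""
    if isinstance(features, FeatureMatrix):
        values = features.values
    elif isinstance(features, pd.DataFrame):
        values = features
    else:
        raise SchemaError("features must be a FeatureMatrix or DataFrame")
    sex = np.asarray(sex, float).ravel()
    if sex.shape[0] != values.shape[0]:
        raise SchemaError(f"sex has {sex.shape[0]} entries for "
                          f"{values.shape[0]} subjects")
    X = np.column_stack([values.to_numpy(float), sex])
    return X, list(values.columns) + ["sex"], values.index


def _check_finite(values: pd.DataFrame) -> None:
    bad = values.index[~np.isfinite(values.to_numpy(float)).all(axis=1)]
    if len(bad):
        raise ValidationError(
            "missing or non-finite feature values for subjects: "
            + ", ".join(map(str, bad[:10]))
            + ("..." if len(bad) > 10 else ""))


def train_predictor(features, demographics: pd.DataFrame, modality: str = "GM",
                    backend: str = "cascade", hyperparams: dict | None = None,
                    seed: int = 0) -> BrainAgePredictor:
    """Fit a brain-age predictor on a training cohort.

    ``features`` may be a full :class:`FeatureMatrix` (restricted internally
    to ``modality``) or a plain DataFrame used as-is.  ``demographics`` must
    carry ``age`` and ``sex`` aligned on subject id.
    """
    if isinstance(features, FeatureMatrix):
        features = features.select(modality).align_to(demographics)
        values = features.values
    else:
        values = features.loc[demographics.index]
    _check_finite(values)
    if len(values) < _MIN_TRAIN_N:
        raise ValidationError(
            f"training needs at least {_MIN_TRAIN_N} subjects, got {len(values)}")
    X, names, _ = _design_matrix(values, demographics["sex"])
    y = demographics["age"].to_numpy(float)

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    dead_mask = scale <= 1e-12 * np.maximum(1.0, np.abs(center))
    dead = [names[j] for j in np.flatnonzero(dead_mask)]
    if dead:
        raise ValidationError("zero-variance features rejected at "
                              f"standardization: {dead[:10]}")
    est = make_backend(backend, hyperparams, seed=seed)
    est.fit((X - center) / scale, y)
    return BrainAgePredictor(
        modality=modality, feature_names=names, center=center, scale=scale,
        backend=est, backend_name=backend,
        training_metadata={"n": len(y), "seed": seed,
                           "hyperparams": dict(hyperparams or {})})


def predict_age(model: BrainAgePredictor, features, sex=None) -> pd.Series:
    """Predict age (years) for each subject; order-normalizes feature columns."""
    if isinstance(features, FeatureMatrix):
        values = features.values
    else:
        values = features
    if sex is None:
        raise SchemaError("per-subject sex is required at predict time")
    provided = list(values.columns)
    expected = [n for n in model.feature_names if n != "sex"]
    missing = sorted(set(expected) - set(provided))
    extra = sorted(set(provided) - set(expected))
    if missing or extra:
        raise SchemaError(
            "feature names do not match the trained model; "
            f"missing: {missing[:10] or 'none'}; unexpected: {extra[:10] or 'none'}")
    values = values[expected]
    _check_finite(values)
    X, _, idx = _design_matrix(values, sex)
    pred = np.asarray(model.backend.predict(model.transform(X)), float).ravel()
    if not np.all(np.isfinite(pred)):
        raise ComputationError("predictor produced non-finite ages")
    return pd.Series(pred, index=idx, name="predicted_age")


def performance_metrics(predicted, actual) -> tuple[float, float]:
    """Pearson correlation and mean absolute error between ages.

    Constant predictions have undefined correlation: rho is returned as NaN
    with a warning while the MAE remains valid.
    """
    predicted = np.asarray(predicted, float).ravel()
    actual = np.asarray(actual, float).ravel()
    if predicted.shape != actual.shape:
        raise SchemaError("predicted and actual must have equal length")
    if predicted.size < 3:
        raise ValidationError("need at least 3 subjects for performance metrics")
    if np.ptp(actual) == 0.0:
        raise ValidationError("actual ages are constant; correlation undefined")
    mae = float(np.mean(np.abs(predicted - actual)))
    if np.ptp(predicted) == 0.0:
        warnings.warn("constant predictions: correlation undefined, reported as NaN")
        return float("nan"), mae
    rho = float(sps.pearsonr(predicted, actual).statistic)
    return rho, mae


@dataclass
class CVReport:
    """Out-of-fold performance of a k-fold cross-validation run."""

    k: int
    per_fold: pd.DataFrame  # columns: fold, n, rho, mae
    pooled_rho: float
    pooled_mae: float
    seed: int
    oof_predictions: pd.Series

    def to_frame(self) -> pd.DataFrame:
        pooled = pd.DataFrame([{"fold": "pooled", "n": int(self.per_fold["n"].sum()),
                                "rho": self.pooled_rho, "mae": self.pooled_mae}])
        return pd.concat([self.per_fold, pooled], ignore_index=True)


def crossvalidate_10fold(features, demographics: pd.DataFrame, modality: str = "GM",
                         backend: str = "cascade", hyperparams: dict | None = None,
                         seed: int = 0, k: int = 10) -> CVReport:
    """Seeded k-fold cross-validation with out-of-fold performance.

    Fold assignment is a seeded shuffle followed by a contiguous split; each
    subject is held out exactly once.
    """
    n = len(demographics)
    if k > n:
        raise ValidationError(f"k={k} folds exceed n={n} subjects")
    if isinstance(features, FeatureMatrix):
        features = features.select(modality).align_to(demographics)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    oof = pd.Series(np.nan, index=demographics.index, name="predicted_age")
    rows = []
    for fold_no, held in enumerate(folds):
        mask = np.zeros(n, bool)
        mask[held] = True
        train_demo = demographics.iloc[~mask]
        test_demo = demographics.iloc[mask]
        values = features.values if isinstance(features, FeatureMatrix) else features
        mdl = train_predictor(values.iloc[~mask], train_demo, modality=modality,
                              backend=backend, hyperparams=hyperparams, seed=seed)
        pred = predict_age(mdl, values.iloc[mask], test_demo["sex"])
        oof.iloc[mask] = pred.to_numpy()
        rho, mae = performance_metrics(pred, test_demo["age"])
        rows.append({"fold": fold_no, "n": int(mask.sum()), "rho": rho, "mae": mae})
    pooled_rho, pooled_mae = performance_metrics(oof, demographics["age"])
    return CVReport(k=k, per_fold=pd.DataFrame(rows), pooled_rho=pooled_rho,
                    pooled_mae=pooled_mae, seed=seed, oof_predictions=oof)
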