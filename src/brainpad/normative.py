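"""Normative modeling of predicted age and peer-referenced scoring.

The normative model is a Gaussian-process regression of brain-predicted age
on (chronological age, sex) fitted in a healthy reference cohort.  At a query
(age, sex) it returns the peer mean and peer SD of predicted age, where the
SD is the *total* predictive SD — latent GP variance plus the estimated
observation-noise variance — because the normative range is meant to describe
where individual observations fall, not where the latent mean lies.

Scores:

* PAD  = predicted_age - age (years)
* cPAD = PAD residualized on age via a linear correction fitted on the
  reference cohort (slope/intercept form)
* nPAD = (predicted_age - peer_mean) / peer_SD  (dimensionless z-score)

nPAD is free of age-related bias by construction: whatever systematic
age-dependent error the predictor makes is absorbed into the peer mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import ComputationError, NotFittedError, SchemaError, ValidationError

__all__ = [
    "NormativeModel",
    "BiasCorrectionFit",
    "fit_normative_gpr",
    "peer_moments",
    "score_pad",
    "score_npad",
    "fit_bias_correction",
    "score_cpad",
    "age_bias_report",
    "compute_pad_scores",
    "pearson_with_p",
]

#: queries this many years beyond the training age range set a warning flag
EXTRAPOLATION_MARGIN = 5.0


@dataclass
class NormativeModel:
    """Fitted GPR normative model of predicted age given (age, sex)."""

    gpr: GaussianProcessRegressor
    age_center: float
    age_scale: float
    age_range: tuple[float, float]
    sex_levels: tuple[int, ...]
    n_train: int

    @property
    def kernel_spec(self) -> str:
        return str(self.gpr.kernel_)

    def moments(self, age, sex):
        """Peer mean, total peer SD, and extrapolation flags at (age, sex)."""
        if self.gpr is None or not hasattr(self.gpr, "X_train_"):
            raise NotFittedError("normative model is not fitted")
        age = np.atleast_1d(np.asarray(age, float))
        sex = np.atleast_1d(np.asarray(sex, float))
        if sex.size == 1 and age.size > 1:
            sex = np.full(age.shape, sex[0])
        if age.shape != sex.shape:
            raise SchemaError("age and sex must align")
        X = np.column_stack([(age - self.age_center) / self.age_scale, sex])
        mean, sd = self.gpr.predict(X, return_std=True)
        if np.any(sd <= 0) or not np.all(np.isfinite(mean)):
            raise ComputationError("normative model produced a non-positive "
                                   "peer SD or non-finite mean")
        lo, hi = self.age_range
        flag = (age < lo - EXTRAPOLATION_MARGIN) | (age > hi + EXTRAPOLATION_MARGIN)
        return mean, sd, flag


def fit_normative_gpr(predicted_age, age, sex, kernel_opts: dict | None = None,
                      seed: int = 0) -> NormativeModel:
    """Fit the GPR normative model on a reference cohort.

    Kernel: constant * RBF over (standardized age, sex dummy) + white noise.
    The age length-scale is initialized at half the age SD with bounds of
    [1, 50] years; the noise variance is initialized at the residual variance
    of a linear pre-fit of predicted age on age and sex.  The optimizer is
    restarted ``n_restarts`` times (default 5) from seeded draws.
    """
    opts = dict(kernel_opts or {})
    predicted_age = np.asarray(predicted_age, float).ravel()
    age = np.asarray(age, float).ravel()
    sex = np.asarray(sex, float).ravel()
    if not (predicted_age.shape == age.shape == sex.shape):
        raise SchemaError("predicted_age, age and sex must align")
    n = predicted_age.size
    if n < 50:
        raise ValidationError(f"normative fit needs at least 50 subjects, got {n}")
    if not np.all(np.isfinite(predicted_age)):
        raise ValidationError("predicted ages must be finite")
    levels = tuple(sorted(np.unique(sex).astype(int)))
    if len(levels) < 2:
        raise ValidationError("both sex levels are required to fit the "
                              "normative model")
    if np.ptp(predicted_age) == 0.0:
        raise ValidationError("predicted age is constant; nothing to model")

    age_center = float(age.mean())
    age_scale = float(age.std()) or 1.0
    Xs = np.column_stack([(age - age_center) / age_scale, sex])

    # linear pre-fit for the noise initialization
    A = np.column_stack([np.ones(n), age, sex])
    resid = predicted_age - A @ np.linalg.lstsq(A, predicted_age, rcond=None)[0]
    var_y = max(float(np.var(predicted_age)), 1e-8)
    # normalize_y=True fits on variance-1 targets: initialize in that scale
    noise0 = max(float(np.var(resid)) / var_y, 1e-10)

    ls_age0 = float(opts.get("length_scale_init", 0.5 * age.std())) / age_scale
    ls_lo, ls_hi = opts.get("length_scale_bounds", (1.0, 50.0))
    ls_bounds = (ls_lo / age_scale, ls_hi / age_scale)
    sex_ls0 = float(opts.get("sex_length_scale", 1.0))
    n_restarts = int(opts.get("n_restarts", 5))

    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=[max(ls_age0, ls_bounds[0]), sex_ls0],
              length_scale_bounds=[ls_bounds, (0.1, 100.0)])
        + WhiteKernel(noise_level=noise0,
                      noise_level_bounds=(max(noise0 * 1e-4, 1e-12), 10.0))
    )
    gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                   n_restarts_optimizer=n_restarts,
                                   random_state=seed, alpha=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gpr.fit(Xs, predicted_age)
    return NormativeModel(gpr=gpr, age_center=age_center, age_scale=age_scale,
                          age_range=(float(age.min()), float(age.max())),
                          sex_levels=levels, n_train=n)


def peer_moments(model: NormativeModel, age, sex):
    """Peer mean and SD of predicted age at (age, sex); warns on extrapolation."""
    mean, sd, flag = model.moments(age, sex)
    if np.any(flag):
        warnings.warn("query ages more than "
                      f"{EXTRAPOLATION_MARGIN:g} years outside the training "
                      "range; extrapolated normative moments flagged")
    return mean, sd, flag


def score_pad(predicted_age, age) -> np.ndarray:
    """Predicted age difference in years: predicted minus chronological."""
    predicted_age = np.asarray(predicted_age, float)
    age = np.asarray(age, float)
    if predicted_age.shape != age.shape:
        raise SchemaError("predicted_age and age must align")
    return predicted_age - age


def score_npad(model: NormativeModel, predicted_age, age, sex) -> np.ndarray:
    """Peer-referenced z-score: (predicted age - peer mean) / peer SD."""
    predicted_age = np.asarray(predicted_age, float).ravel()
    mean, sd, _ = model.moments(age, sex)
    if predicted_age.shape != mean.shape:
        raise SchemaError("predicted_age must align with age and sex")
    return (predicted_age - mean) / sd


@dataclass
class BiasCorrectionFit:
    """Linear age-bias correction for PAD, fitted on the reference cohort."""

    alpha: float  # years of PAD per year of age
    beta: float   # intercept, years
    fit_n: int


def fit_bias_correction(pad, age) -> BiasCorrectionFit:
    """OLS of PAD on age; cPAD subtracts the fitted trend."""
    pad = np.asarray(pad, float).ravel()
    age = np.asarray(age, float).ravel()
    if pad.shape != age.shape:
        raise SchemaError("pad and age must align")
    if pad.size < 30:
        raise ValidationError("bias correction needs at least 30 subjects")
    if np.ptp(age) == 0.0:
        raise ValidationError("age is constant; bias slope is unidentifiable")
    res = sps.linregress(age, pad)
    return BiasCorrectionFit(alpha=float(res.slope), beta=float(res.intercept),
                             fit_n=pad.size)


def score_cpad(fit: BiasCorrectionFit, pad, age) -> np.ndarray:
    pad = np.asarray(pad, float)
    age = np.asarray(age, float)
    return pad - (fit.alpha * age + fit.beta)


def pearson_with_p(x, y, method: str = "auto", n_perm: int = 10000,
                   seed: int = 0) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value.

    ``method="t"`` uses the t approximation, ``"permutation"`` an exact-style
    permutation test; ``"auto"`` permutes below n=30 where the t approximation
    is shaky.  Constant inputs give (NaN, NaN).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise SchemaError("inputs must align")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan"), float("nan")
    if method == "auto":
        method = "permutation" if x.size < 30 else "t"
    if method == "t":
        res = sps.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        res = sps.permutation_test(
            (x,), lambda xp: sps.pearsonr(xp, y).statistic,
            permutation_type="pairings", n_resamples=n_perm,
            alternative="two-sided", random_state=rng)
        return float(sps.pearsonr(x, y).statistic), float(res.pvalue)
    raise ValidationError(f"unknown p-value method '{method}'")


def age_bias_report(metrics: dict[str, np.ndarray], age, cohort: str,
                    method: str = "t") -> pd.DataFrame:
    """Correlate each PAD-family metric with chronological age.

    ``metrics`` maps metric name (e.g. ``"PAD"``, ``"cPAD"``, ``"nPAD"``) to
    a per-subject vector.  Returns one row per metric with Pearson rho and a
    two-sided p; degenerate (constant) metrics yield NaN with a note.
    """
    age = np.asarray(age, float).ravel()
    if age.size < 3:
        raise ValidationError("bias report needs at least 3 subjects")
    rows = []
    for name, vals in metrics.items():
        vals = np.asarray(vals, float).ravel()
        if vals.shape != age.shape:
            raise SchemaError(f"metric '{name}' does not align with age")
        rho, p = pearson_with_p(vals, age, method=method)
        note = "" if np.isfinite(rho) else "constant metric: correlation undefined"
        rows.append({"metric": name, "cohort": cohort, "rho": rho,
                     "p": p, "n": age.size, "note": note})
    return pd.DataFrame(rows)


def compute_pad_scores(predicted_age: pd.Series, cohort: pd.DataFrame,
                       modality: str, normative: NormativeModel,
                       bias_fit: BiasCorrectionFit | None = None) -> pd.DataFrame:
    """Assemble the tidy per-subject score table for one modality.

    Columns: subject_id (index), modality, predicted_age, pad, cpad, npad,
    extrapolation_flag.  cPAD is NaN when no bias-correction fit is supplied.
    """
    age = cohort["age"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float)
    pred = predicted_age.loc[cohort.index].to_numpy(float)
    pad = score_pad(pred, age)
    mean, sd, flag = normative.moments(age, sex)
    npad = (pred - mean) / sd
    cpad = score_cpad(bias_fit, pad, age) if bias_fit is not None else np.full_like(pad, np.nan)
    return pd.DataFrame({
        "modality": modality, "predicted_age": pred, "pad": pad,
        "cpad": cpad, "npad": npad, "extrapolation_flag": flag,
    }, index=cohort.index)
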