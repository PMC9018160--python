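"""Per-feature group x feature interaction mapping on nPAD.

For each ROI feature, an OLS model

    npad ~ feature + group + feature*group + age + sex + education

is fitted on the pooled case/control sample (group coded control = 0,
case = 1, so the interaction coefficient reads as the case-specific slope
increment).  The interaction term's t-test gives the p-value and its Cohen's
f-squared is computed from the R-squared of the full model against the same
model without the interaction term.  A scan over all features of a modality
applies Benjamini-Hochberg correction within that scan and ranks by effect
size, identifying features whose relation to normative brain-age deviation
is distinctly different in cases.

The per-feature fits use closed-form least squares for speed; they agree
with a general-purpose OLS implementation to machine precision (covered by
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ComputationError, SchemaError, ValidationError
from .stats import bh_adjust
from .synthetic import FeatureMatrix, GM_MODALITIES, WM_MODALITIES

__all__ = [
    "cohens_f2",
    "fit_feature_interaction",
    "scan_all_features",
    "InteractionResult",
]


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """Cohen's f-squared for an added term: (R2f - R2r) / (1 - R2f)."""
    if not (np.isfinite(r2_full) and np.isfinite(r2_reduced)):
        raise ValidationError("R-squared values must be finite")
    if r2_full >= 1.0:
        raise ValidationError("R-squared of the full model must be below 1")
    if r2_reduced < 0.0 or r2_full < 0.0:
        raise ValidationError("R-squared values must be non-negative")
    if r2_reduced > r2_full + 1e-12:
        raise ValidationError("reduced-model R-squared exceeds full-model "
                              "R-squared; models are not nested as expected")
    return max(r2_full - r2_reduced, 0.0) / (1.0 - r2_full)


@dataclass
class InteractionResult:
    coefficient: float
    std_coefficient: float
    se: float
    t: float
    p: float
    f2: float
    r2_full: float
    r2_reduced: float
    n: int


def _ols(X: np.ndarray, y: np.ndarray):
    """Least-squares fit returning (coef, residual SS, XtX inverse)."""
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise ComputationError("singular design in interaction model") from exc
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    return coef, float(resid @ resid), XtX_inv


def fit_feature_interaction(feature, npad, group, age, sex, education
                            ) -> InteractionResult:
    """Fit the interaction model for one feature.

    ``group`` may be 0/1 codes or labels containing ``"case"``/``"control"``.
    """
    feature = np.asarray(feature, float).ravel()
    npad = np.asarray(npad, float).ravel()
    age = np.asarray(age, float).ravel()
    sex = np.asarray(sex, float).ravel()
    education = np.asarray(education, float).ravel()
    g = _group_codes(group)
    n = feature.size
    if not all(v.shape == feature.shape for v in (npad, g, age, sex, education)):
        raise SchemaError("all inputs must align")
    if np.unique(g).size < 2:
        raise ValidationError("both groups must be present")
    if np.ptp(feature) == 0.0:
        raise ValidationError("zero-variance feature")
    mask = np.isfinite(feature) & np.isfinite(npad) & np.isfinite(age) \
        & np.isfinite(sex) & np.isfinite(education)
    feature, npad, g, age, sex, education = (
        v[mask] for v in (feature, npad, g, age, sex, education))
    n = feature.size
    if n < 10:
        raise ValidationError("too few complete cases for the interaction model")

    inter = feature * g
    X_full = np.column_stack([np.ones(n), feature, g, inter, age, sex, education])
    X_red = np.delete(X_full, 3, axis=1)
    coef, rss_full, XtX_inv = _ols(X_full, npad)
    _, rss_red, _ = _ols(X_red, npad)
    tss = float(np.sum((npad - npad.mean()) ** 2))
    if tss == 0.0:
        raise ValidationError("constant outcome; nothing to model")
    r2_full = 1.0 - rss_full / tss
    r2_red = 1.0 - rss_red / tss
    df_resid = n - X_full.shape[1]
    if df_resid <= 0:
        raise ValidationError("not enough residual degrees of freedom")
    sigma2 = rss_full / df_resid
    se = float(np.sqrt(sigma2 * XtX_inv[3, 3]))
    t = float(coef[3] / se)
    p = float(2.0 * sps.t.sf(abs(t), df_resid))
    std_coef = float(coef[3] * inter.std() / npad.std()) if npad.std() > 0 else np.nan
    return InteractionResult(
        coefficient=float(coef[3]), std_coefficient=std_coef, se=se, t=t, p=p,
        f2=cohens_f2(r2_full, r2_red), r2_full=r2_full, r2_reduced=r2_red, n=n)


def _group_codes(group) -> np.ndarray:
    arr = np.asarray(group).ravel()
    if arr.dtype.kind in "ifub":
        codes = arr.astype(float)
        if not set(np.unique(codes)) <= {0.0, 1.0}:
            raise ValidationError("numeric group codes must be 0 (control) "
                                  "or 1 (case)")
        return codes
    mapping = {"control": 0.0, "case": 1.0}
    try:
        return np.array([mapping[str(v)] for v in arr])
    except KeyError as exc:
        raise ValidationError(f"unknown group label {exc}; expected "
                              "'case'/'control' or 0/1 codes") from exc


_SCAN_FAMILIES = {"GM": GM_MODALITIES, "WM": WM_MODALITIES,
                  "multimodal": GM_MODALITIES + WM_MODALITIES}


def scan_all_features(features: FeatureMatrix, npad_by_modality: dict,
                      cohort: pd.DataFrame, modalities: tuple[str, ...] = ("GM", "WM"),
                      bh_scope: str = "per_modality", alpha: float = 0.05
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Scan every feature of each model family against its nPAD score.

    GM features (volumes and cortical thickness alike — no pre-filtering by
    feature type) are paired with nPAD-GM, WM features with nPAD-WM.  Returns
    the full record table ranked within each scan by f-squared (ties broken
    by feature name) plus a log of skipped features.  ``bh_scope`` is
    ``"per_modality"`` (default: one BH family per scan) or ``"pooled"``.
    """
    if bh_scope not in ("per_modality", "pooled"):
        raise ValidationError("bh_scope must be 'per_modality' or 'pooled'")
    age = cohort["age"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float)
    edu = cohort["education"].to_numpy(float)
    g = _group_codes(cohort["group"])
    rows, skipped = [], []
    for scan in modalities:
        if scan not in _SCAN_FAMILIES:
            raise SchemaError(f"unknown modality scan '{scan}'")
        if scan not in npad_by_modality:
            raise SchemaError(f"npad scores missing for modality '{scan}'")
        npad = np.asarray(pd.Series(npad_by_modality[scan]).loc[cohort.index], float)
        fam = features.select(scan)
        for name in fam.feature_names:
            col = fam.values[name].to_numpy(float)
            try:
                res = fit_feature_interaction(col, npad, g, age, sex, edu)
            except ValidationError as exc:
                skipped.append(f"{scan}:{name}: {exc}")
                continue
            rows.append({"feature": name, "measure": str(features.modality[name]),
                         "scan": scan, "coefficient": res.coefficient,
                         "std_coefficient": res.std_coefficient, "se": res.se,
                         "f2": res.f2, "p": res.p, "n": res.n})
    out = pd.DataFrame(rows)
    if out.empty:
        return out, skipped
    family = (out["scan"].to_numpy() if bh_scope == "per_modality"
              else np.zeros(len(out), dtype=int))
    out["p_corrected"] = bh_adjust(out["p"].to_numpy(), family=family)
    out["significant"] = out["p_corrected"] < alpha
    out = out.sort_values(["scan", "f2", "feature"],
                          ascending=[True, False, True], kind="stable")
    out["rank"] = out.groupby("scan").cumcount() + 1
    return out.reset_index(drop=True), skipped
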