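"""Group-level statistics for PAD-family scores.

Covers the downstream analyses around the normative scores: ANCOVA group
comparisons with covariate adjustment, paired tests between modalities,
comparison of two correlations by Fisher's r-to-z, within-group sex
differences, a 3-SD outlier exclusion rule for clinical variables, phenotype
regressions, and Benjamini-Hochberg FDR correction.

Multiple-comparison families follow a per-analysis-block policy by default:
the three modalities of a group comparison form one family, the sex tests
within a group another, and each phenotype model class (its named predictors
across all nPAD outcomes) another.  The policy is an argument everywhere it
matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, SchemaError, ValidationError

__all__ = [
    "GroupComparison",
    "bh_adjust",
    "ancova_group_comparison",
    "paired_modality_test",
    "modality_correlation_comparison",
    "sex_difference_analysis",
    "exclude_outliers",
    "phenotype_regressions",
    "PHENOTYPE_MODEL_CLASSES",
]

#: predictors per phenotype regression model class; FSIQ controls education
PHENOTYPE_MODEL_CLASSES = {
    "clinical_factors": ["duration", "onset_age", "dose"],
    "symptom_severity": ["panss_pos", "panss_neg", "panss_gen"],
    "fsiq": ["fsiq"],
}


def bh_adjust(p_values, family=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    ``family`` optionally assigns each p-value to a correction family; the
    step-up adjustment is applied within each family independently.
    """
    p = np.asarray(p_values, float).ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    out = np.empty_like(p)
    if family is None:
        fam = np.zeros(p.size, dtype=int)
    else:
        fam = np.asarray(family)
        if fam.shape != p.shape:
            raise SchemaError("family labels must align with p-values")
    for lab in pd.unique(fam):
        idx = np.flatnonzero(fam == lab)
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return np.minimum(out, 1.0)


@dataclass
class GroupComparison:
    """ANCOVA comparison of one metric between two groups."""

    metric: str
    group_stats: pd.DataFrame  # index: group, columns: n, mean, sd
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    covariates: tuple[str, ...]
    p_corrected: float | None = None

    def to_row(self) -> dict:
        row = {"metric": self.metric, "F": self.f_statistic,
               "df_num": self.df_num, "df_den": self.df_den,
               "p": self.p_value, "p_corrected": self.p_corrected,
               "covariates": "+".join(self.covariates) or "none"}
        for g, r in self.group_stats.iterrows():
            row[f"mean_{g}"] = r["mean"]
            row[f"sd_{g}"] = r["sd"]
            row[f"n_{g}"] = int(r["n"])
        return row


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name a minimal offender set by greedy scan
        bad = []
        base = np.ones((len(X), 1))
        for col in X.columns:
            cand = np.column_stack([base, X[col].to_numpy(float)])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(col)
            else:
                base = cand
        raise ComputationError(f"singular design; collinear columns: {bad}")


def ancova_group_comparison(metric, group, covariates: pd.DataFrame | None = None,
                            covariate_names: tuple[str, ...] | None = None,
                            metric_name: str = "metric") -> GroupComparison:
    """ANCOVA of a metric between two groups, adjusting covariates.

    Fits ``metric ~ group + covariates`` by OLS and reports the Type-II
    F-test of the group term (with no interactions in the model Type-II and
    Type-III coincide).
    """
    metric = np.asarray(metric, float).ravel()
    group = pd.Series(np.asarray(group).ravel())
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValidationError(f"exactly two groups required, got {levels}")
    df = pd.DataFrame({"y": metric, "grp": group.to_numpy()})
    cov_names: list[str] = []
    if covariates is not None:
        use = list(covariate_names) if covariate_names is not None \
            else list(covariates.columns)
        for c in use:
            if c not in covariates.columns:
                raise SchemaError(f"covariate '{c}' missing from table")
            df[c] = np.asarray(covariates[c], float)
            cov_names.append(c)
    if df.isna().any().any():
        raise ValidationError("ANCOVA requires complete cases")
    if cov_names:
        _check_collinearity(df[cov_names])
    formula = "y ~ C(grp)" + "".join(f" + {c}" for c in cov_names)
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(grp)"]
    stats = df.groupby("grp")["y"].agg(n="count", mean="mean",
                                       sd=lambda v: v.std(ddof=1))
    return GroupComparison(
        metric=metric_name, group_stats=stats,
        f_statistic=float(row["F"]), df_num=int(row["df"]),
        df_den=int(table.loc["Residual", "df"]), p_value=float(row["PR(>F)"]),
        covariates=tuple(cov_names))


def paired_modality_test(npad_a, npad_b) -> tuple[float, int, float]:
    """Paired t-test between two aligned score vectors; df = n - 1.

    Zero-variance differences are degenerate: t is reported as signed
    infinity (or 0 for identical vectors) with p accordingly.
    """
    a = np.asarray(npad_a, float).ravel()
    b = np.asarray(npad_b, float).ravel()
    if a.shape != b.shape:
        raise SchemaError("paired vectors must align")
    n = a.size
    if n < 3:
        raise ValidationError("paired test needs at least 3 pairs")
    d = a - b
    df = n - 1
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(d[0]) * np.inf), df, 0.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), df, float(res.pvalue)


def _fisher_z(r: float) -> float:
    return float(np.arctanh(r))


def modality_correlation_comparison(npad_gm, npad_wm, group) -> pd.DataFrame:
    """Per-group Pearson correlation of two score vectors, plus the
    between-group difference tested by Fisher's r-to-z.

    Returns one row per group and a final ``difference`` row with the z
    statistic and two-sided p.
    """
    x = np.asarray(npad_gm, float).ravel()
    y = np.asarray(npad_wm, float).ravel()
    g = pd.Series(np.asarray(group).ravel())
    if not (x.shape == y.shape == (len(g),)):
        raise SchemaError("scores and group labels must align")
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValidationError(f"exactly two groups required, got {levels}")
    rows, zs, ns = [], [], []
    for lab in levels:
        m = (g == lab).to_numpy()
        n = int(m.sum())
        if n <= 3:
            raise ValidationError(f"group '{lab}' needs more than 3 subjects")
        res = sps.pearsonr(x[m], y[m])
        rows.append({"group": lab, "n": n, "rho": float(res.statistic),
                     "p": float(res.pvalue)})
        zs.append(_fisher_z(float(res.statistic)))
        ns.append(n)
    z = (zs[0] - zs[1]) / np.sqrt(1.0 / (ns[0] - 3) + 1.0 / (ns[1] - 3))
    p_diff = float(2.0 * sps.norm.sf(abs(z)))
    rows.append({"group": "difference", "n": sum(ns), "rho": np.nan,
                 "p": p_diff, "z": float(z)})
    return pd.DataFrame(rows)


def sex_difference_analysis(npad_by_modality: pd.DataFrame, sex, group,
                            within_group: str | None = None) -> pd.DataFrame:
    """Welch two-sample sex comparison of each score column within groups.

    ``npad_by_modality`` has one column per modality.  BH correction is
    applied across the modalities within each group (one family per group).
    Single-sex groups are skipped with a note.  Corrected p is capped at 1.
    """
    sex = np.asarray(sex).ravel()
    g = pd.Series(np.asarray(group).ravel())
    if not (len(npad_by_modality) == sex.size == len(g)):
        raise SchemaError("scores, sex and group labels must align")
    groups = [within_group] if within_group is not None else sorted(g.unique())
    rows = []
    for lab in groups:
        m = (g == lab).to_numpy()
        sexes = np.unique(sex[m])
        for col in npad_by_modality.columns:
            v = npad_by_modality[col].to_numpy(float)[m]
            if sexes.size < 2:
                rows.append({"group": lab, "modality": col, "t": np.nan,
                             "p": np.nan, "note": "single-sex group: skipped",
                             "mean_male": np.nan, "mean_female": np.nan})
                continue
            male = v[sex[m] == 1]
            female = v[sex[m] == 0]
            res = sps.ttest_ind(male, female, equal_var=False)
            rows.append({"group": lab, "modality": col,
                         "t": float(res.statistic), "p": float(res.pvalue),
                         "note": "", "mean_male": float(male.mean()),
                         "mean_female": float(female.mean()),
                         "sd_male": float(male.std(ddof=1)),
                         "sd_female": float(female.std(ddof=1))})
    out = pd.DataFrame(rows)
    out["p_corrected"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_corrected"] = bh_adjust(out.loc[ok, "p"].to_numpy(),
                                               family=out.loc[ok, "group"].to_numpy())
    return out


def exclude_outliers(cohort: pd.DataFrame, fields, threshold_sd: float = 3.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude subjects whose listed fields exceed ``threshold_sd`` sample SDs.

    Single pass: means and SDs come from the full pre-exclusion sample, and a
    subject is excluded iff *any* listed field deviates by more than the
    threshold.  Returns the filtered cohort and an exclusion log with one row
    per (subject, offending field).
    """
    fields = list(fields)
    for f in fields:
        if f not in cohort.columns:
            raise SchemaError(f"field '{f}' missing from cohort")
        if not np.issubdtype(np.asarray(cohort[f]).dtype, np.number):
            raise ValidationError(f"field '{f}' is not numeric")
    log_rows = []
    drop = pd.Series(False, index=cohort.index)
    for f in fields:
        v = cohort[f].astype(float)
        mu, sd = v.mean(), v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        z = (v - mu) / sd
        bad = z.abs() > threshold_sd
        drop |= bad.fillna(False)
        for sid in cohort.index[bad.fillna(False)]:
            log_rows.append({"subject_id": sid, "field": f,
                             "value": float(v.loc[sid]), "z": float(z.loc[sid])})
    filtered = cohort.loc[~drop]
    if len(filtered) == 0:
        raise ComputationError("all subjects excluded by the outlier rule")
    log = pd.DataFrame(log_rows, columns=["subject_id", "field", "value", "z"])
    return filtered, log


def phenotype_regressions(npad_by_modality: pd.DataFrame, cohort: pd.DataFrame,
                          model_classes: dict | None = None,
                          bh_policy: str = "per_class") -> pd.DataFrame:
    """Multiple regressions of each nPAD outcome on phenotype classes.

    For each outcome column, three models are fitted: clinical factors
    (duration + onset age + dose), symptom severity (the three PANSS scores),
    and FSIQ (controlling education).  Complete cases only; the number used
    is logged per model.  BH correction is applied within each model class
    across its named predictors and all outcomes (``bh_policy="per_class"``),
    or across everything (``"pooled"``).  Covariates (education) are not part
    of the correction family.
    """
    classes = model_classes or PHENOTYPE_MODEL_CLASSES
    rows = []
    for cls, predictors in classes.items():
        covars = ["education"] if cls == "fsiq" else []
        needed = predictors + covars
        for col in needed:
            if col not in cohort.columns:
                raise SchemaError(f"phenotype column '{col}' missing from cohort")
        for outcome in npad_by_modality.columns:
            df = pd.concat([npad_by_modality[outcome].rename("y"),
                            cohort[needed]], axis=1, join="inner").dropna()
            n = len(df)
            if n < len(needed) + 2:
                raise ValidationError(
                    f"too few complete cases ({n}) for model '{cls}'")
            X = df[needed]
            _check_collinearity(X)
            fit = sm.OLS(df["y"], sm.add_constant(X)).fit()
            for pred in predictors:
                rows.append({"model_class": cls, "outcome": outcome,
                             "predictor": pred,
                             "estimate": float(fit.params[pred]),
                             "se": float(fit.bse[pred]),
                             "p": float(fit.pvalues[pred]), "n": n})
    out = pd.DataFrame(rows)
    family = (out["model_class"].to_numpy() if bh_policy == "per_class"
              else np.zeros(len(out), dtype=int))
    out["p_corrected"] = bh_adjust(out["p"].to_numpy(), family=family)
    return out
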