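"""End-to-end pipeline wiring from synthetic cohorts to result tables.

Each stage function takes a :class:`~brainpad.io.RunConfig`, reads the
artifacts of its upstream stages from the run directory, writes its own
tables plus a deterministic manifest, and returns the paths it wrote.
``run_pipeline`` chains every stage.  All randomness is derived from the
config seed, so a rerun with the same config reproduces the deterministic
stages byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import interactions as interactions_mod
from . import stats as stats_mod
from .errors import ConfigurationError
from .io import (RunConfig, ensure_writable, read_cohort, read_features,
                 write_cohort, write_features, write_manifest)
from .model import crossvalidate_10fold, predict_age, train_predictor
from .normative import (age_bias_report, compute_pad_scores,
                        fit_bias_correction, fit_normative_gpr, score_pad)
from .synthetic import CohortGenerator, FeatureMatrix, write_truth_json

log = logging.getLogger("brainpad")

_COHORTS = ("reference", "test", "case", "control")


def _dir(config: RunConfig, sub: str) -> Path:
    d = Path(config.outdir) / sub
    d.mkdir(parents=True, exist_ok=True)
    return d


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise ConfigurationError(
            f"missing upstream artifact {path}; run '{producer}' first")
    return path


def simulate(config: RunConfig) -> list[Path]:
    """Generate all four synthetic cohorts and write them as CSV."""
    d = _dir(config, "cohorts")
    gen = CohortGenerator(config.synthetic.replace(seed=config.seed))
    outputs = []
    for name, (cohort, fm) in (
            ("reference", gen.reference()), ("test", gen.test()),
            ("case", gen.case()), ("control", gen.control())):
        cpath, fpath = d / f"{name}.csv", d / f"{name}_features.csv"
        for p in (cpath, fpath):
            ensure_writable(p, config.force)
        write_cohort(cohort, cpath)
        write_features(fm, fpath)
        outputs += [cpath, fpath, d / f"{name}_features_meta.csv"]
    write_truth_json(gen, d / "truth.json")
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(config.canonical_dict(), fh, sort_keys=True)
    outputs += [d / "truth.json", d / "config.yaml"]
    write_manifest(Path(config.outdir), "simulate", config, [], outputs)
    return outputs


def _load_cohort(config: RunConfig, name: str):
    d = Path(config.outdir) / "cohorts"
    cpath = _require(d / f"{name}.csv", "simulate")
    fpath = _require(d / f"{name}_features.csv", "simulate")
    cohort = read_cohort(cpath)
    fm = read_features(fpath).align_to(cohort)
    return cohort, fm


def train(config: RunConfig) -> list[Path]:
    """Train one predictor per modality and report 10-fold CV performance."""
    d = _dir(config, "models")
    cohort, fm = _load_cohort(config, "reference")
    outputs = []
    cv_rows = []
    for modality in config.modalities:
        mdl = train_predictor(fm, cohort, modality=modality,
                              backend=config.backend,
                              hyperparams=config.model_hyperparams,
                              seed=config.seed)
        joblib.dump(mdl, d / f"predictor_{modality}.joblib")
        report = crossvalidate_10fold(fm, cohort, modality=modality,
                                      backend=config.backend,
                                      hyperparams=config.model_hyperparams,
                                      seed=config.seed, k=config.cv_folds)
        frame = report.to_frame()
        frame.insert(0, "modality", modality)
        cv_rows.append(frame)
        log.info("CV %s: pooled rho=%.3f MAE=%.2f", modality,
                 report.pooled_rho, report.pooled_mae)
    cv_path = d / "cv_report.csv"
    ensure_writable(cv_path, config.force)
    pd.concat(cv_rows, ignore_index=True).to_csv(cv_path, index=False,
                                                 float_format="%.10g")
    outputs.append(cv_path)
    write_manifest(Path(config.outdir), "train", config, [], outputs)
    return outputs


def normative(config: RunConfig) -> list[Path]:
    """Fit the GPR normative model and PAD bias correction per modality."""
    d = _dir(config, "normative")
    models_dir = Path(config.outdir) / "models"
    cohort, fm = _load_cohort(config, "reference")
    outputs = []
    for modality in config.modalities:
        mdl = joblib.load(_require(models_dir / f"predictor_{modality}.joblib",
                                   "train"))
        pred = predict_age(mdl, fm.select(modality), cohort["sex"])
        norm = fit_normative_gpr(pred, cohort["age"], cohort["sex"],
                                 kernel_opts=config.kernel_opts,
                                 seed=config.seed)
        bias = fit_bias_correction(score_pad(pred, cohort["age"]), cohort["age"])
        joblib.dump({"normative": norm, "bias": bias},
                    d / f"normative_{modality}.joblib")
        meta = {"modality": modality, "kernel": norm.kernel_spec,
                "n": norm.n_train, "bias_alpha": bias.alpha,
                "bias_beta": bias.beta}
        mpath = d / f"normative_{modality}.json"
        pd.Series(meta).to_json(mpath)
        outputs.append(mpath)
    write_manifest(Path(config.outdir), "normative", config, [], outputs)
    return outputs


def score(config: RunConfig, cohorts: tuple[str, ...] = _COHORTS) -> list[Path]:
    """Score every cohort with PAD, cPAD and nPAD per modality."""
    d = _dir(config, "scores")
    models_dir = Path(config.outdir) / "models"
    norm_dir = Path(config.outdir) / "normative"
    tables = []
    bias_rows = []
    for modality in config.modalities:
        mdl = joblib.load(_require(models_dir / f"predictor_{modality}.joblib",
                                   "train"))
        bundle = joblib.load(_require(norm_dir / f"normative_{modality}.joblib",
                                      "normative"))
        for name in cohorts:
            cohort, fm = _load_cohort(config, name)
            pred = predict_age(mdl, fm.select(modality), cohort["sex"])
            scores = compute_pad_scores(pred, cohort, modality,
                                        bundle["normative"], bundle["bias"])
            scores.insert(0, "cohort", name)
            tables.append(scores)
            bias_rows.append(age_bias_report(
                {"PAD": scores["pad"], "cPAD": scores["cpad"],
                 "nPAD": scores["npad"]},
                cohort["age"], f"{name}/{modality}"))
    spath = d / "pad_scores.csv"
    bpath = d / "bias_report.csv"
    for p in (spath, bpath):
        ensure_writable(p, config.force)
    pd.concat(tables).to_csv(spath, float_format="%.10g")
    pd.concat(bias_rows, ignore_index=True).to_csv(bpath, index=False,
                                                   float_format="%.10g")
    write_manifest(Path(config.outdir), "score", config, [], [spath, bpath])
    return [spath, bpath]


def _load_scores(config: RunConfig) -> pd.DataFrame:
    path = _require(Path(config.outdir) / "scores" / "pad_scores.csv", "score")
    return pd.read_csv(path, index_col=0)


def _npad_wide(scores: pd.DataFrame, cohorts: tuple[str, ...],
               column: str = "npad") -> pd.DataFrame:
    sub = scores[scores["cohort"].isin(cohorts)]
    return sub.pivot_table(index=sub.index, columns="modality", values=column,
                           sort=False)


def compare(config: RunConfig) -> list[Path]:
    """Case/control comparisons: ANCOVA, paired tests, correlation contrast,
    sex differences."""
    d = _dir(config, "stats")
    scores = _load_scores(config)
    case, _ = _load_cohort(config, "case")
    control, _ = _load_cohort(config, "control")
    demo = pd.concat([case[["age", "sex", "education", "group"]],
                      control[["age", "sex", "education", "group"]]])
    npad = _npad_wide(scores, ("case", "control")).loc[demo.index]
    cpad = _npad_wide(scores, ("case", "control"), "cpad").loc[demo.index]

    comp_rows = []
    for metric, wide, covs in (("nPAD", npad, ("education",)),
                               ("cPAD", cpad, ("sex", "education"))):
        block = []
        for modality in wide.columns:
            gc = stats_mod.ancova_group_comparison(
                wide[modality], demo["group"], demo, covs,
                metric_name=f"{metric}-{modality}")
            block.append(gc)
        ps = stats_mod.bh_adjust([g.p_value for g in block])
        for g, pc in zip(block, ps):
            g.p_corrected = float(pc)
            comp_rows.append(g.to_row())
    comp_path = d / "group_comparisons.csv"
    ensure_writable(comp_path, config.force)
    pd.DataFrame(comp_rows).to_csv(comp_path, index=False, float_format="%.10g")

    paired_rows = []
    if {"GM", "WM"} <= set(npad.columns):
        for label, idx in (("case", case.index), ("control", control.index)):
            t, dof, p = stats_mod.paired_modality_test(
                npad.loc[idx, "GM"], npad.loc[idx, "WM"])
            paired_rows.append({"group": label, "t": t, "df": dof, "p": p})
        corr = stats_mod.modality_correlation_comparison(
            npad["GM"], npad["WM"], demo["group"])
    else:
        corr = pd.DataFrame()
    paired_path = d / "paired_tests.csv"
    pd.DataFrame(paired_rows).to_csv(paired_path, index=False,
                                     float_format="%.10g")
    corr_path = d / "correlation_comparison.csv"
    corr.to_csv(corr_path, index=False, float_format="%.10g")

    sexdiff = stats_mod.sex_difference_analysis(npad, demo["sex"], demo["group"])
    sex_path = d / "sex_differences.csv"
    sexdiff.to_csv(sex_path, index=False, float_format="%.10g")

    outputs = [comp_path, paired_path, corr_path, sex_path]
    write_manifest(Path(config.outdir), "compare", config, [], outputs)
    return outputs


def phenotype(config: RunConfig) -> list[Path]:
    """Outlier exclusion plus phenotype regressions on case nPAD scores."""
    d = _dir(config, "stats")
    scores = _load_scores(config)
    case, _ = _load_cohort(config, "case")
    fields = [f for f in config.outlier_fields if f in case.columns]
    kept, excl_log = stats_mod.exclude_outliers(case, fields,
                                                config.outlier_threshold_sd)
    npad = _npad_wide(scores, ("case",)).loc[kept.index]
    table = stats_mod.phenotype_regressions(npad, kept,
                                            bh_policy=config.bh_policy)
    reg_path = d / "phenotype_regressions.csv"
    excl_path = d / "exclusions.csv"
    for p in (reg_path, excl_path):
        ensure_writable(p, config.force)
    table.to_csv(reg_path, index=False, float_format="%.10g")
    excl_log.to_csv(excl_path, index=False, float_format="%.10g")
    write_manifest(Path(config.outdir), "phenotype", config, [],
                   [reg_path, excl_path])
    return [reg_path, excl_path]


def interactions(config: RunConfig) -> list[Path]:
    """Per-feature group x feature interaction scans with Cohen's f2."""
    d = _dir(config, "interactions")
    scores = _load_scores(config)
    case, case_fm = _load_cohort(config, "case")
    control, control_fm = _load_cohort(config, "control")
    demo = pd.concat([case[["age", "sex", "education", "group"]],
                      control[["age", "sex", "education", "group"]]])
    values = pd.concat([case_fm.values, control_fm.values])
    fm = FeatureMatrix(values.loc[demo.index], case_fm.modality,
                       case_fm.interaction_features)
    npad = _npad_wide(scores, ("case", "control")).loc[demo.index]
    table, skipped = interactions_mod.scan_all_features(
        fm, {m: npad[m] for m in npad.columns}, demo,
        modalities=tuple(s for s in config.interaction_scans
                         if s in npad.columns))
    full_path = d / "interaction_full.csv"
    sig_path = d / "interaction_significant.csv"
    for p in (full_path, sig_path):
        ensure_writable(p, config.force)
    table.to_csv(full_path, index=False, float_format="%.10g")
    sig = table[table["significant"]] if len(table) else table
    sig.to_csv(sig_path, index=False, float_format="%.10g")
    if skipped:
        with open(d / "skipped_features.txt", "w") as fh:
            fh.write("\n".join(skipped) + "\n")
    write_manifest(Path(config.outdir), "interactions", config, [],
                   [full_path, sig_path])
    return [full_path, sig_path]


_STAGES = (simulate, train, normative, score, compare, phenotype, interactions)


def run_pipeline(config: RunConfig) -> list[Path]:
    """Run every stage in order; returns all written table paths."""
    outputs = []
    for stage in _STAGES:
        log.info("pipeline stage: %s", stage.__name__)
        outputs += stage(config)
    return outputs
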