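"""Group statistics against closed-form and matrix-algebra oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import brainpad as bp
from brainpad.stats import (ancova_group_comparison, bh_adjust,
                            exclude_outliers, modality_correlation_comparison,
                            paired_modality_test, phenotype_regressions,
                            sex_difference_analysis)


def bh_oracle(p):
    """Textbook step-up: q_i = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


class TestBHAdjust:
    def test_hand_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        np.testing.assert_allclose(bh_adjust([0.001, 0.3, 0.8]),
                                   [0.003, 0.45, 0.8], atol=1e-12)
        assert bh_adjust([0.5])[0] == pytest.approx(0.5)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_family_labels_split_correction(self):
        p = np.array([0.01, 0.04, 0.01, 0.04])
        fam = np.array(["a", "a", "b", "b"])
        out = bh_adjust(p, family=fam)
        np.testing.assert_allclose(out[:2], bh_adjust(p[:2]))
        np.testing.assert_allclose(out[2:], bh_adjust(p[2:]))

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(bp.ValidationError):
                bh_adjust(bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                    max_size=25))
    def test_matches_oracle_monotone_idempotent(self, p):
        out = bh_adjust(p)
        np.testing.assert_allclose(out, bh_oracle(p), atol=1e-12)
        # monotone: ordering of adjusted values preserves ordering of raw p
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)
        # idempotent on already-adjusted values
        np.testing.assert_allclose(bh_adjust(out), bh_oracle(out), atol=1e-12)

    def test_fdr_controlled_on_mixture(self):
        rng = np.random.default_rng(0)
        fdrs = []
        for _ in range(300):
            null_p = rng.uniform(size=40)
            alt_p = rng.uniform(size=10) * 1e-4
            p = np.concatenate([null_p, alt_p])
            q = bh_adjust(p)
            sig = q < 0.05
            fp = sig[:40].sum()
            fdrs.append(fp / max(sig.sum(), 1))
        assert np.mean(fdrs) <= 0.05 + 0.02


class TestANCOVA:
    def _fixture(self):
        # hand-checkable 8-subject fixture
        y = np.array([1.0, 2.2, 1.4, 2.7, 3.1, 3.9, 3.6, 4.4])
        grp = np.array(["a"] * 4 + ["b"] * 4)
        cov = pd.DataFrame({"edu": [10, 12, 11, 13, 10, 12, 11, 13.0]})
        return y, grp, cov

    def test_f_matches_matrix_algebra_oracle(self):
        y, grp, cov = self._fixture()
        res = ancova_group_comparison(y, grp, cov, ("edu",))
        # oracle: extra-sum-of-squares F comparing full vs no-group model,
        # built from raw normal equations
        g = (grp == "b").astype(float)
        X_full = np.column_stack([np.ones(8), g, cov["edu"]])
        X_red = np.column_stack([np.ones(8), cov["edu"]])

        def rss(X):
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            return r @ r
        df_den = 8 - X_full.shape[1]
        f_oracle = (rss(X_red) - rss(X_full)) / (rss(X_full) / df_den)
        assert res.f_statistic == pytest.approx(f_oracle, abs=1e-10)
        assert res.df_num == 1 and res.df_den == df_den
        p_oracle = sps.f.sf(f_oracle, 1, df_den)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_no_covariates_equals_oneway_anova(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)])
        grp = np.array(["x"] * 20 + ["y"] * 25)
        res = ancova_group_comparison(y, grp)
        f, p = sps.f_oneway(y[:20], y[20:])
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_collinear_covariates_named(self):
        y, grp, cov = self._fixture()
        cov = cov.assign(edu2=cov["edu"] * 2.0)
        with pytest.raises(bp.ComputationError, match="edu2"):
            ancova_group_comparison(y, grp, cov, ("edu", "edu2"))

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            y = rng.normal(size=40)
            grp = np.array(["a"] * 20 + ["b"] * 20)
            cov = pd.DataFrame({"edu": rng.normal(size=40)})
            res = ancova_group_comparison(y, grp, cov, ("edu",))
            rejections += res.p_value < 0.05
        rate = rejections / n_sim
        assert 0.02 <= rate <= 0.08

    def test_power_at_cohort_scale(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            y = np.concatenate([rng.normal(1.0, 1.0, 147),
                                rng.normal(0.0, 1.0, 130)])
            grp = np.array(["case"] * 147 + ["control"] * 130)
            cov = pd.DataFrame({"edu": rng.normal(15, 2, 277)})
            res = ancova_group_comparison(y, grp, cov, ("edu",))
            hits += res.p_value < 0.05
        assert hits == 50


class TestPairedAndCorrelation:
    def test_identical_vectors(self):
        t, df, p = paired_modality_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_constant_nonzero_difference_degenerate(self):
        t, df, p = paired_modality_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=147), rng.normal(size=147)
        t, df, p = paired_modality_test(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(147))
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert df == 146
        assert p == pytest.approx(2 * sps.t.sf(abs(t_oracle), 146), abs=1e-10)

    def test_equal_correlations_give_z_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        xx, yy = np.concatenate([x, x]), np.concatenate([y, y])
        grp = np.array(["a"] * 40 + ["b"] * 40)
        res = modality_correlation_comparison(xx, yy, grp)
        diff = res[res["group"] == "difference"].iloc[0]
        assert diff["z"] == pytest.approx(0.0, abs=1e-12)
        assert diff["p"] == pytest.approx(1.0)

    def test_fisher_z_formula(self):
        rng = np.random.default_rng(6)
        n1, n2 = 100, 100
        x1 = rng.normal(size=n1); y1 = 0.5 * x1 + rng.normal(size=n1)
        x2 = rng.normal(size=n2); y2 = rng.normal(size=n2)
        res = modality_correlation_comparison(
            np.concatenate([x1, x2]), np.concatenate([y1, y2]),
            np.array(["a"] * n1 + ["b"] * n2))
        r1 = sps.pearsonr(x1, y1).statistic
        r2 = sps.pearsonr(x2, y2).statistic
        z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / 97 + 1 / 97)
        diff = res[res["group"] == "difference"].iloc[0]
        assert diff["z"] == pytest.approx(z, abs=1e-10)
        assert diff["p"] == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-12)

    def test_fisher_z_agrees_with_permutation_oracle(self):
        # label-permutation null of the correlation difference
        rng = np.random.default_rng(7)
        n = 100
        x1 = rng.normal(size=n); y1 = 0.45 * x1 + rng.normal(size=n)
        x2 = rng.normal(size=n); y2 = rng.normal(size=n)
        x, y = np.concatenate([x1, x2]), np.concatenate([y1, y2])
        grp = np.array(["a"] * n + ["b"] * n)
        res = modality_correlation_comparison(x, y, grp)
        p_fisher = res[res["group"] == "difference"].iloc[0]["p"]

        def rdiff(labels):
            m = labels == "a"
            return (sps.pearsonr(x[m], y[m]).statistic
                    - sps.pearsonr(x[~m], y[~m]).statistic)
        obs = rdiff(grp)
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            count += abs(rdiff(rng.permutation(grp))) >= abs(obs)
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_fisher - p_perm) < 0.03


class TestSexDifference:
    def test_null_world_corrected_p_near_one(self):
        rng = np.random.default_rng(8)
        scores = pd.DataFrame({"GM": rng.normal(size=200),
                               "WM": rng.normal(size=200)})
        sex = rng.integers(0, 2, 200)
        grp = np.array(["case"] * 200)
        out = sex_difference_analysis(scores, sex, grp)
        assert (out["p_corrected"] >= out["p"] - 1e-12).all()
        assert (out["p_corrected"] <= 1.0).all()

    def test_single_sex_group_skipped_with_note(self):
        scores = pd.DataFrame({"GM": np.arange(10.0)})
        out = sex_difference_analysis(scores, np.zeros(10),
                                      np.array(["case"] * 10))
        assert out["note"].str.contains("single-sex").all()
        assert out["p"].isna().all()

    def test_planted_gm_only_male_offset_detected(self, study):
        # male cases get an extra GM-only aging offset: the GM sex test in
        # cases should reject, the WM test should not (the pattern of a
        # male-specific gray-matter effect)
        # interaction-free world (same reference law, so the study's fitted
        # instrument applies) to keep case nPAD variance at its base level
        gen = bp.CohortGenerator(study.config.replace(n_interaction_features=0))
        hits_gm, hits_wm = 0, 0
        for d in range(6):
            case, cfm = gen.case(draw=d)
            vals = cfm.values.copy()
            male = case["sex"] == 1
            gm_cols = [c for c in vals.columns
                       if cfm.modality[c] in ("volume", "thickness")]
            m = gen.feature_model
            beta = pd.Series(m.beta, index=m.names)[gm_cols]
            # extra 8 years of GM aging for male cases
            vals.loc[male, gm_cols] += (8.0 * beta).to_numpy()
            fm = bp.FeatureMatrix(vals, cfm.modality)
            npad = pd.DataFrame({
                mod: bp.score_npad(
                    study.normative[mod],
                    bp.predict_age(study.predictors[mod], fm.select(mod),
                                   case["sex"]),
                    case["age"], case["sex"])
                for mod in ("GM", "WM")}, index=case.index)
            out = sex_difference_analysis(npad, case["sex"],
                                          np.array(["case"] * len(case)))
            row = out.set_index("modality")
            hits_gm += row.loc["GM", "p_corrected"] < 0.05
            hits_wm += row.loc["WM", "p_corrected"] < 0.05
        assert hits_gm >= 5
        assert hits_wm <= 2


class TestOutlierExclusion:
    def test_all_within_one_sd_no_exclusion(self):
        df = pd.DataFrame({"dose": [10.0, 11.0, 10.5, 9.5, 10.2]},
                          index=[f"s{i}" for i in range(5)])
        kept, log = exclude_outliers(df, ["dose"])
        assert len(kept) == 5 and log.empty

    def test_planted_extreme_value_excluded_exactly(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"dose": rng.normal(300, 30, 50),
                           "fsiq": rng.normal(95, 10, 50)},
                          index=[f"s{i}" for i in range(50)])
        df.loc["s7", "dose"] = 300 + 10 * 30
        kept, log = exclude_outliers(df, ["dose", "fsiq"])
        assert "s7" not in kept.index
        assert len(kept) == 49
        assert set(log["subject_id"]) == {"s7"}
        assert set(log["field"]) == {"dose"}

    def test_single_pass_uses_pre_exclusion_moments(self):
        # a massive outlier inflates the SD; a moderate 3.5-SD-of-clean-data
        # point must survive because the single pass measures SD with the
        # outlier included
        clean = np.concatenate([np.repeat([-1.0, 1.0], 10), [3.5]])
        df = pd.DataFrame({"v": np.concatenate([clean, [1000.0]])},
                          index=[f"s{i}" for i in range(22)])
        kept, log = exclude_outliers(df, ["v"])
        assert "s21" not in kept.index  # the planted huge outlier
        assert "s20" in kept.index      # the moderate point survives
        assert len(log) == 1

    def test_exclusion_fraction_matches_normal_theory(self):
        rng = np.random.default_rng(10)
        n, reps, frac = 500, 40, []
        for _ in range(reps):
            df = pd.DataFrame({"a": rng.normal(size=n),
                               "b": rng.normal(size=n)})
            kept, _ = exclude_outliers(df, ["a", "b"])
            frac.append(1 - len(kept) / n)
        # per-field exceedance ~0.27%; union over two fields ~0.54%
        assert abs(np.mean(frac) - 0.0054) < 0.004

    def test_errors(self):
        df = pd.DataFrame({"grp": ["a", "b"]})
        with pytest.raises(bp.ValidationError):
            exclude_outliers(df, ["grp"])
        with pytest.raises(bp.SchemaError):
            exclude_outliers(df, ["nope"])


class TestPhenotypeRegressions:
    def test_coefficients_match_normal_equations_oracle(self):
        # tiny fixture: one outcome, clinical-factor model
        rng = np.random.default_rng(11)
        n = 12
        cohort = pd.DataFrame({
            "duration": rng.uniform(1, 15, n),
            "onset_age": rng.uniform(18, 30, n),
            "dose": rng.uniform(100, 600, n),
            "panss_pos": rng.uniform(7, 30, n),
            "panss_neg": rng.uniform(7, 30, n),
            "panss_gen": rng.uniform(16, 50, n),
            "fsiq": rng.uniform(70, 120, n),
            "education": rng.uniform(9, 18, n),
        }, index=[f"s{i}" for i in range(n)])
        npad = pd.DataFrame({"WM": rng.normal(size=n)}, index=cohort.index)
        table = phenotype_regressions(npad, cohort)
        X = np.column_stack([np.ones(n), cohort["duration"],
                             cohort["onset_age"], cohort["dose"]])
        y = npad["WM"].to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        got = table[(table.model_class == "clinical_factors")
                    & (table.outcome == "WM")].set_index("predictor")
        for j, pred in enumerate(["duration", "onset_age", "dose"], start=1):
            assert got.loc[pred, "estimate"] == pytest.approx(beta[j],
                                                              abs=1e-10)
            assert got.loc[pred, "se"] == pytest.approx(se[j], abs=1e-10)

    def test_bh_family_is_per_model_class(self):
        rng = np.random.default_rng(12)
        n = 60
        cohort = pd.DataFrame({
            c: rng.uniform(1, 10, n) for c in
            ("duration", "onset_age", "dose", "panss_pos", "panss_neg",
             "panss_gen", "fsiq", "education")})
        cohort.index = [f"s{i}" for i in range(n)]
        npad = pd.DataFrame({"GM": rng.normal(size=n),
                             "WM": rng.normal(size=n)}, index=cohort.index)
        table = phenotype_regressions(npad, cohort)
        for cls, sub in table.groupby("model_class"):
            np.testing.assert_allclose(sub["p_corrected"],
                                       bh_oracle(sub["p"].to_numpy()),
                                       atol=1e-12)

    def test_null_phenotypes_type_one_error(self):
        rng = np.random.default_rng(13)
        hits, total = 0, 0
        for _ in range(60):
            n = 80
            cohort = pd.DataFrame({
                c: rng.normal(10, 2, n) for c in
                ("duration", "onset_age", "dose", "panss_pos", "panss_neg",
                 "panss_gen", "fsiq", "education")})
            cohort.index = [f"s{i}" for i in range(n)]
            npad = pd.DataFrame({"WM": rng.normal(size=n)},
                                index=cohort.index)
            table = phenotype_regressions(npad, cohort)
            hits += (table["p"] < 0.05).sum()
            total += len(table)
        rate = hits / total
        assert 0.02 <= rate <= 0.09

    def test_rank_deficiency_named(self):
        rng = np.random.default_rng(14)
        n = 30
        cohort = pd.DataFrame({
            "duration": rng.uniform(1, 10, n),
            "onset_age": np.full(n, 23.0),
            "dose": rng.uniform(100, 500, n)})
        cohort["onset_age"] = cohort["duration"] * 2  # collinear
        cohort.index = [f"s{i}" for i in range(n)]
        npad = pd.DataFrame({"WM": rng.normal(size=n)}, index=cohort.index)
        with pytest.raises(bp.ComputationError, match="onset_age"):
            phenotype_regressions(
                npad, cohort,
                model_classes={"clinical_factors":
                               ["duration", "onset_age", "dose"]})
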