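import numpy as np
import pandas as pd
import pytest

from brainsex import (adjust_pvalues, anova_marginal, anova_sequential, fit_lme,
                      menarche_groups, pds_average, results_frame, run_association,
                      site_filter)
from brainsex import tables as T
from brainsex.longitudinal import (MENARCHE_EXCLUDED, MENARCHE_NO_NO, MENARCHE_ONSET,
                                   MODEL_SPECS, AssociationResult, ModelSpec)


class TestPdsAverage:
    def test_floor(self):
        assert pds_average([1, 1, 1, 1, 1]) == 1.0

    def test_menarche_coded_four(self):
        # items (3,3,3,3) plus menstruation "Yes" (=4) -> 3.2
        assert pds_average([3, 3, 3, 3, 4]) == pytest.approx(3.2)

    def test_direct_mean(self):
        assert pds_average([2, 3, 3, 2, 4]) == pytest.approx(2.8)

    def test_missing_items_use_available(self):
        assert pds_average([2, np.nan, 4]) == pytest.approx(3.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pds_average([np.nan, np.nan])


def _puberty_table(answers):
    rows = []
    for sid, (b, f) in answers.items():
        for ses, a in [(T.BASELINE, b), (T.FOLLOWUP, f)]:
            if a is None:
                continue
            rows.append({T.SUBJECT: sid, T.SESSION: ses, T.SEX: "F",
                         "menarche": a})
    return pd.DataFrame(rows)


class TestMenarcheGroups:
    def test_paper_defined_groups(self):
        tab = _puberty_table({"a": ("no", "no"), "b": ("no", "yes"),
                              "c": ("yes", "yes"), "d": ("yes", "no")})
        g = menarche_groups(tab).set_index(T.SUBJECT)["menarche_group"]
        assert g["a"] == MENARCHE_NO_NO
        assert g["b"] == MENARCHE_ONSET
        assert g["c"] == MENARCHE_EXCLUDED
        assert g["d"] == MENARCHE_EXCLUDED

    def test_missing_session_excluded_with_reason(self):
        tab = _puberty_table({"a": ("no", None)})
        g = menarche_groups(tab)
        assert g.loc[0, "menarche_group"] == MENARCHE_EXCLUDED
        assert "missing" in g.loc[0, "reason"]

    def test_males_ignored(self):
        tab = _puberty_table({"a": ("no", "yes")})
        tab2 = tab.copy()
        tab2[T.SEX] = "M"
        tab2[T.SUBJECT] = "m1"
        g = menarche_groups(pd.concat([tab, tab2]))
        assert set(g[T.SUBJECT]) == {"a"}


class TestSiteFilter:
    def _data(self, counts):
        rows = []
        for site, n in counts.items():
            rows += [{T.SITE: site, "x": i} for i in range(n)]
        return pd.DataFrame(rows)

    def test_nineteen_dropped_twenty_kept(self):
        out = site_filter(self._data({"a": 19, "b": 20}))
        assert set(out[T.SITE]) == {"b"}
        assert len(out) == 20

    def test_all_dropped_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            site_filter(self._data({"a": 5, "b": 3}))

    def test_single_large_site_unchanged(self):
        data = self._data({"a": 30})
        out = site_filter(data)
        pd.testing.assert_frame_equal(out, data)


def _longit_data(n_subj=60, seed=0, age_beta=0.0, re_sd=0.05, noise=0.05,
                 sex="F", extra=None, mirrored_noise=False):
    """Two-session outcome table.  ``mirrored_noise`` makes the two session
    residuals exact negatives, which pins the ML random-intercept variance
    to its zero boundary (for OLS-oracle tests)."""
    rng = np.random.default_rng(seed)
    age0 = rng.uniform(108, 168, n_subj)
    re = rng.normal(0, re_sd, n_subj)
    eps0 = rng.normal(0, noise, n_subj)
    rows = []
    for k, (s, gap) in enumerate([(T.BASELINE, 0.0), (T.FOLLOWUP, 24.0)]):
        age = age0 + gap
        eps = (eps0 if k == 0 else -eps0) if mirrored_noise \
            else rng.normal(0, noise, n_subj)
        y = 0.5 + age_beta * (age - 138) + re + eps
        df = pd.DataFrame({T.SUBJECT: [f"S{i:03d}" for i in range(n_subj)],
                           T.SESSION: s, T.SEX: sex, T.AGE: age,
                           T.EULER: rng.normal(-50, 10, n_subj).round(),
                           T.SITE: "site01", "p_female": y})
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    if extra:
        for k, fn in extra.items():
            out[k] = fn(out, rng)
    return out


class TestFitLme:
    def test_zero_subject_variance_recovered(self):
        data = _longit_data(seed=1, re_sd=0.0, noise=0.1, mirrored_noise=True)
        with pytest.warns(UserWarning, match="near zero"):
            fit = fit_lme(MODEL_SPECS["age_lme"], data)
        assert fit.sigma2_u < 0.01 * fit.sigma2_e

    def test_fixed_effects_match_ols_when_re_null(self):
        data = _longit_data(seed=2, re_sd=0.0, noise=0.1, age_beta=0.002,
                            mirrored_noise=True)
        fit = fit_lme(MODEL_SPECS["age_lme"], data)
        beta_ols, *_ = np.linalg.lstsq(fit.X, fit.y, rcond=None)
        np.testing.assert_allclose(fit.fe_params, beta_ols, atol=1e-4)

    def test_age_slope_recovery_with_ci_coverage(self):
        # known positive slope; sign correct and 95% CI covers truth in
        # >= 90% of 20 seeds
        truth = 0.003
        hits = signs = 0
        for seed in range(20):
            data = _longit_data(seed=seed, age_beta=truth, re_sd=0.08, noise=0.05)
            fit = fit_lme(MODEL_SPECS["age_lme"], data)
            est, se = fit.coef("age_months")
            signs += est > 0
            hits += abs(est - truth) < 1.96 * se
        assert signs >= 18
        assert hits >= 18

    def test_aliased_terms_named(self):
        data = _longit_data(seed=3)
        data[T.EULER] = data[T.AGE]   # euler aliased with age
        with pytest.raises(ValueError, match="aliased"):
            fit_lme(MODEL_SPECS["age_lme"], data)


def _ols_sequential_f(X, y, slices, terms):
    """Independent OLS type-I oracle via raw RSS differences."""
    def rss(cols):
        b, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        r = y - X[:, cols] @ b
        return r @ r
    n, p = X.shape
    mse = rss(list(range(p))) / (n - p)
    fs = {}
    cols = [0]
    prev = rss(cols)
    for t in terms:
        sl = slices[t]
        cols = cols + list(range(sl.start, sl.stop))
        new = rss(cols)
        fs[t] = ((prev - new) / (sl.stop - sl.start)) / mse
        prev = new
    return fs


class TestAnova:
    def test_type_one_equals_ols_f_when_re_null(self):
        data = _longit_data(seed=4, re_sd=0.0, noise=0.1, age_beta=0.001,
                            mirrored_noise=True)
        fit = fit_lme(MODEL_SPECS["age_lme"], data)
        res = anova_sequential(fit)
        oracle = _ols_sequential_f(fit.X, fit.y, fit.slices, fit.terms)
        for _, row in res.table.iterrows():
            assert row["F"] == pytest.approx(oracle[row["term"]], abs=1e-6)

    def test_orthogonal_design_type_one_equals_type_two(self):
        rng = np.random.default_rng(5)
        n = 80
        # balanced orthogonal two-way layout in custom spec terms
        data = pd.DataFrame({
            T.SUBJECT: [f"S{i:03d}" for i in range(n)],
            T.SESSION: T.BASELINE,
            T.SEX: "F",
            T.AGE: np.tile([-1.0, 1.0], n // 2),
            T.EULER: np.repeat([-1.0, 1.0], n // 2),
            T.SITE: "site01",
        })
        data["p_female"] = 0.5 + 0.1 * data[T.AGE] + 0.05 * data[T.EULER] \
            + rng.normal(0, 0.05, n)
        spec = ModelSpec("toy", ("age_months", "euler"), random_intercept=False)
        fit = fit_lme(spec, data)
        t1 = anova_sequential(fit).table.set_index("term")["F"]
        t2 = anova_marginal(fit).table.set_index("term")["F"]
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy(), rtol=1e-9)

    def _correlated_fixture(self, seed=6):
        rng = np.random.default_rng(seed)
        n = 120
        age = rng.uniform(108, 168, n)
        pds = 1 + 3 / (1 + np.exp(-(age - 138) / 15)) + rng.normal(0, 0.3, n)
        data = pd.DataFrame({
            T.SUBJECT: [f"S{i:03d}" for i in range(n)], T.SESSION: T.BASELINE,
            T.SEX: "F", T.AGE: age, T.EULER: rng.normal(-50, 10, n),
            T.SITE: "site01", "pds_average": pds,
        })
        data["p_female"] = 0.5 + 0.004 * (age - 138) + rng.normal(0, 0.08, n)
        return data

    def test_sequential_f_depends_on_order(self):
        data = self._correlated_fixture()
        a = ModelSpec("a", ("pds_average", "age_months"), random_intercept=False)
        b = ModelSpec("b", ("age_months", "pds_average"), random_intercept=False)
        fa = anova_sequential(fit_lme(a, data)).table.set_index("term")["F"]
        fb = anova_sequential(fit_lme(b, data)).table.set_index("term")["F"]
        assert fa["pds_average"] != pytest.approx(fb["pds_average"], rel=1e-3)

    def test_marginal_invariant_to_main_effect_order(self):
        data = self._correlated_fixture()
        a = ModelSpec("a", ("pds_average", "age_months"), random_intercept=False)
        b = ModelSpec("b", ("age_months", "pds_average"), random_intercept=False)
        fa = anova_marginal(fit_lme(a, data)).table.set_index("term")["F"]
        fb = anova_marginal(fit_lme(b, data)).table.set_index("term")["F"]
        for t in ("pds_average", "age_months"):
            assert fa[t] == pytest.approx(fb[t], rel=1e-9)

    def test_type_two_controls_shared_variance_across_seeds(self):
        # PDS has no effect beyond age: type-II PDS F non-significant in
        # >= 80% of 20 seeds while type-I with PDS first is significant
        t1_sig = t2_sig = 0
        for seed in range(20):
            data = self._correlated_fixture(seed)
            spec = MODEL_SPECS["pds_lme"]
            data2 = pd.concat([data, data.assign(
                **{T.SESSION: T.FOLLOWUP, T.AGE: data[T.AGE] + 24,
                   "p_female": data["p_female"] + 0.004 * 24,
                   "pds_average": np.minimum(data["pds_average"] + 0.5, 4)})],
                ignore_index=True)
            fit = fit_lme(spec, data2)
            p1 = anova_sequential(fit).table.set_index("term")["p"]["pds_average"]
            p2 = anova_marginal(fit).table.set_index("term")["p"]["pds_average"]
            t1_sig += p1 < 0.05
            t2_sig += p2 >= 0.05
        assert t1_sig >= 16
        assert t2_sig >= 16

    def test_f_invariant_to_affine_outcome_rescale(self):
        data = _longit_data(seed=7, age_beta=0.002)
        fit1 = fit_lme(MODEL_SPECS["age_lme"], data)
        data2 = data.assign(p_female=3.0 * data["p_female"] + 10.0)
        fit2 = fit_lme(MODEL_SPECS["age_lme"], data2)
        f1 = anova_sequential(fit1).table["F"].to_numpy()
        f2 = anova_sequential(fit2).table["F"].to_numpy()
        np.testing.assert_allclose(f1, f2, rtol=1e-4)


class TestAdjustPvalues:
    def _result(self, pvals):
        table = pd.DataFrame({"term": [f"t{i}" for i in range(len(pvals))],
                              "F": 1.0, "num_df": 1, "den_df": 10.0, "p": pvals})
        return AssociationResult("age_lme", "I", {}, table)

    def test_single_p_unchanged(self):
        out = adjust_pvalues([self._result([0.03])])
        assert out[0].table["p_adj"].iloc[0] == pytest.approx(0.03)

    def test_bh_step_up_worked_example(self):
        out = adjust_pvalues([self._result([0.01, 0.02, 0.03, 0.04])])
        np.testing.assert_allclose(out[0].table["p_adj"], [0.04] * 4)

    def test_all_ones(self):
        out = adjust_pvalues([self._result([1.0, 1.0, 1.0])])
        assert (out[0].table["p_adj"] == 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            adjust_pvalues([self._result([1.5])])

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            adjust_pvalues([])


class TestRunAssociation:
    def _probs_meta(self, seed=8):
        data = _longit_data(n_subj=80, seed=seed, age_beta=0.003, re_sd=0.08)
        meta = data[[T.SUBJECT, T.SESSION, T.SEX, T.AGE, T.EULER, T.SITE]].copy()
        probs = pd.concat([
            data[[T.SUBJECT, T.SESSION]].assign(feature_set=fs,
                                                p_female=data["p_female"])
            for fs in ("limbic", "nonlimbic")], ignore_index=True)
        return probs, meta

    def test_pooled_sexes_refused(self):
        probs, meta = self._probs_meta()
        with pytest.raises(ValueError, match="stratified by sex"):
            run_association("age_lme", probs, meta, "both")

    def test_tidy_output_covers_models_terms_and_types(self):
        probs, meta = self._probs_meta()
        res = run_association("age_lme", probs, meta, "F")
        frame = results_frame(res)
        assert set(frame["feature_set"]) == {"limbic", "nonlimbic"}
        assert set(frame["anova_type"]) == {"I", "II"}
        assert "p_adj" in frame.columns
        terms = frame[frame["anova_type"] == "I"]["term"].unique()
        assert list(MODEL_SPECS["age_lme"].terms) == [t for t in terms]

    def test_join_loss_warns(self):
        probs, meta = self._probs_meta()
        # keep both sessions but only a quarter of subjects
        keep = meta[T.SUBJECT].unique()[:20]
        probs = probs[probs[T.SUBJECT].isin(keep)]
        with pytest.warns(UserWarning, match="join lost"):
            run_association("age_lme", probs, meta, "F")

    def test_menarche_null_calibration(self):
        # menarche assigned as pure noise: onset term non-significant in
        # >= 90% of 20 seeds
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 200)
            data = _longit_data(n_subj=70, seed=seed + 200, age_beta=0.002,
                                re_sd=0.08)
            groups = pd.DataFrame({
                T.SUBJECT: data[T.SUBJECT].unique(),
                "menarche_group": rng.choice([MENARCHE_NO_NO, MENARCHE_ONSET],
                                             data[T.SUBJECT].nunique())})
            meta = data[[T.SUBJECT, T.SESSION, T.SEX, T.AGE, T.EULER, T.SITE]] \
                .merge(groups, on=T.SUBJECT)
            probs = data[[T.SUBJECT, T.SESSION]].assign(feature_set="limbic",
                                                        p_female=data["p_female"])
            res = run_association("menarche_lme", probs, meta, "F", adjust=False)
            p = [r for r in res if r.anova_type == "I"][0] \
                .table.set_index("term")["p"]["menarche_onset"]
            hits += p >= 0.05
        assert hits >= 18
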