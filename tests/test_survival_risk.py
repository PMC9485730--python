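import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from irlncpair.errors import (
    DegeneratePredictorError,
    DegenerateStratificationError,
    SingularInformationError,
    ValidationError,
)
from irlncpair.expression_io import ClinicalTable
from irlncpair.pair_encoding import encode_pairs, pair_ratio_filter
from irlncpair.survival_risk import (
    HIGH,
    LOW,
    RiskModel,
    cox_clinical,
    cox_multivariate,
    cox_univariate,
    hazard_ratio_from_fit,
    km_logrank,
    lasso_cox_select,
    risk_score,
    stratify,
    time_roc,
)
from irlncpair.synthetic_data import generate_survival_cohort
from conftest import no_censoring_clinical, small_sim_config


class TestHazardArithmetic:
    @pytest.mark.parametrize(
        "beta,hr", [(0.789, 2.201), (0.863, 2.371), (0.0, 1.0)]
    )
    def test_printed_hazard_ratios(self, beta, hr):
        # 3-dp agreement up to rounding of the printed beta itself
        got, _, _ = hazard_ratio_from_fit(beta, 0.3)
        assert got == pytest.approx(hr, abs=0.0005 * (1 + hr))

    def test_ci_identities_hold_for_fits(self, survival_small):
        surv, clin = survival_small
        pm = encode_pairs(surv, ["LNC0001", "LNC0002", "LNC0003", "LNC0004"])
        for lbl in pm.labels:
            fit = cox_univariate(pm.indicators.loc[lbl].astype(float), clin,
                                 name=lbl)
            assert fit.hr == pytest.approx(np.exp(fit.beta))
            assert fit.hr_lo == pytest.approx(np.exp(fit.beta - 1.959964 * fit.se))
            assert fit.hr_hi == pytest.approx(np.exp(fit.beta + 1.959964 * fit.se))
            assert fit.hr_lo <= fit.hr <= fit.hr_hi


def direct_partial_loglik(beta, x, time, event):
    """Partial likelihood written out subject-by-subject (no ties in the
    fixtures that use this)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


class TestCoxUnivariate:
    def test_four_subject_fit_matches_direct_maximum(self):
        x = [1.0, 0.0, 1.0, 0.0]
        clin = no_censoring_clinical([1.0, 2.0, 3.0, 4.0])
        fit = cox_univariate(pd.Series(x, index=clin.samples), clin, name="x")
        res = optimize.minimize_scalar(
            lambda b: -direct_partial_loglik(b, x, [1, 2, 3, 4], [1, 1, 1, 1]),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta == pytest.approx(res.x, abs=1e-4)

    def test_efron_equals_breslow_without_ties(self, survival_small):
        surv, clin = survival_small
        x = surv.values.loc["LNC0001"] > surv.values.loc["LNC0002"]
        fe = cox_univariate(x.astype(float), clin, name="x", ties="efron")
        fb = cox_univariate(x.astype(float), clin, name="x", ties="breslow")
        assert fe.beta == pytest.approx(fb.beta, abs=1e-5)
        assert fe.se == pytest.approx(fb.se, rel=1e-4)

    def test_null_wald_p_uniform(self):
        hits, n_rep = 0, 150
        for seed in range(n_rep):
            rg = np.random.default_rng(3000 + seed)
            clin = no_censoring_clinical(
                rg.exponential(30, 60), (rg.random(60) < 0.6).astype(int)
            )
            x = pd.Series(rg.normal(size=60), index=clin.samples)
            hits += cox_univariate(x, clin, name="x").p <= 0.05
        assert stats.binomtest(hits, n_rep, 0.05).pvalue > 0.001

    def test_invariances(self):
        rg = np.random.default_rng(8)
        t = rg.exponential(20, 80)
        e = (rg.random(80) < 0.7).astype(int)
        x = rg.normal(size=80)
        base = cox_univariate(
            pd.Series(x, index=[f"P{i}" for i in range(80)]),
            no_censoring_clinical(t, e), name="x",
        ).beta
        scaled_time = cox_univariate(
            pd.Series(x, index=[f"P{i}" for i in range(80)]),
            no_censoring_clinical(t * 7.3, e), name="x",
        ).beta
        shifted_x = cox_univariate(
            pd.Series(x + 5.0, index=[f"P{i}" for i in range(80)]),
            no_censoring_clinical(t, e), name="x",
        ).beta
        assert scaled_time == pytest.approx(base, abs=1e-8)
        assert shifted_x == pytest.approx(base, abs=1e-6)

    def test_constant_predictor_rejected(self):
        clin = no_censoring_clinical([1, 2, 3, 4])
        with pytest.raises(DegeneratePredictorError):
            cox_univariate(pd.Series([1.0] * 4, index=clin.samples), clin)

    def test_no_events_rejected(self):
        clin = no_censoring_clinical([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValidationError):
            cox_univariate(pd.Series([1.0, 0, 1, 0], index=clin.samples), clin)


class TestCoxMultivariate:
    def test_single_predictor_equals_univariate(self, survival_small):
        surv, clin = survival_small
        x = (surv.values.loc["LNC0001"] > surv.values.loc["LNC0002"]).astype(float)
        uni = cox_univariate(x, clin, name="x")
        multi = cox_multivariate(x.to_frame("x"), clin)[0]
        assert multi.beta == pytest.approx(uni.beta, abs=1e-8)
        assert multi.se == pytest.approx(uni.se, rel=1e-6)

    def test_duplicated_predictor_raises_singular(self, survival_small):
        surv, clin = survival_small
        x = (surv.values.loc["LNC0001"] > surv.values.loc["LNC0002"]).astype(float)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(SingularInformationError, match="a.*b|b.*a"):
            cox_multivariate(X, clin)


class TestLasso:
    def test_full_shrinkage_gives_empty_selection(self, survival_small):
        surv, clin = survival_small
        pm = pair_ratio_filter(
            encode_pairs(surv, [f"LNC{i + 1:04d}" for i in range(8)])
        )
        with pytest.warns(UserWarning, match="no pairs"):
            res = lasso_cox_select(pm, clin, seed=0, alphas=np.array([1e6, 5e5]))
        assert res.selected == []

    def test_seeded_selection_deterministic(self, survival_small):
        surv, clin = survival_small
        pm = pair_ratio_filter(
            encode_pairs(surv, [f"LNC{i + 1:04d}" for i in range(8)])
        )
        r1 = lasso_cox_select(pm, clin, seed=7)
        r2 = lasso_cox_select(pm, clin, seed=7)
        assert r1.selected == r2.selected
        assert r1.alpha_min == r2.alpha_min
        np.testing.assert_array_equal(r1.cv_deviance, r2.cv_deviance)

    def test_weak_penalty_keeps_strong_planted_pair(self, survival_small):
        surv, clin = survival_small
        pm = pair_ratio_filter(
            encode_pairs(surv, [f"LNC{i + 1:04d}" for i in range(8)])
        )
        res = lasso_cox_select(pm, clin, seed=1)
        assert "LNC0001|LNC0002" in res.selected

    def test_active_set_shrinks_along_path(self, survival_small):
        surv, clin = survival_small
        pm = pair_ratio_filter(
            encode_pairs(surv, [f"LNC{i + 1:04d}" for i in range(8)])
        )
        res = lasso_cox_select(pm, clin, seed=1)
        nonzero = (res.coef_path != 0).sum(axis=0).to_numpy()
        alphas = res.coef_path.columns.to_numpy(float)
        order = np.argsort(alphas)  # increasing penalty
        assert np.all(np.diff(nonzero[order]) <= 0)


class TestRiskScore:
    MODEL = RiskModel(
        ["LINC01121|FAM167A-AS1", "ADAMTS9-AS2|MGC12916",
         "MIR124-2HG|FAM167A-AS1"],
        [0.687, 0.863, 0.419],
    )

    def _pm(self, values):
        import irlncpair.pair_encoding as pe
        from irlncpair.expression_io import ExpressionMatrix

        genes = ["LINC01121", "FAM167A-AS1", "ADAMTS9-AS2", "MGC12916",
                 "MIR124-2HG"]
        em = ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=["S1"])
        )
        return pe.encode_pairs(em, genes)

    def test_all_indicators_one_gives_full_sum(self):
        # expression ordered so every model pair fires
        pm = self._pm([[5.0], [1.0], [4.0], [2.0], [3.0]])
        score = risk_score(self.MODEL, pm)
        assert score.iloc[0] == pytest.approx(0.687 + 0.863 + 0.419)

    def test_all_indicators_zero_gives_zero(self):
        pm = self._pm([[1.0], [5.0], [2.0], [4.0], [0.5]])
        score = risk_score(self.MODEL, pm)
        assert score.iloc[0] == 0.0

    def test_score_additive_over_submodels(self):
        pm = self._pm([[5.0], [1.0], [4.0], [2.0], [3.0]])
        half1 = RiskModel(self.MODEL.pairs[:1], self.MODEL.coefs[:1])
        half2 = RiskModel(self.MODEL.pairs[1:], self.MODEL.coefs[1:])
        total = risk_score(half1, pm) + risk_score(half2, pm)
        pd.testing.assert_series_equal(
            total, risk_score(self.MODEL, pm), check_names=False
        )

    def test_unresolvable_pair_raises(self):
        pm = self._pm([[5.0], [1.0], [4.0], [2.0], [3.0]])
        with pytest.raises(KeyError):
            risk_score(RiskModel(["NOPE|ALSO"], [1.0]), pm)


class TestStratify:
    def test_median_rule_simple(self):
        scores = pd.Series([0, 0, 1, 1], index=list("abcd"), dtype=float)
        out = stratify(scores)
        assert out["cutoff"].iloc[0] == 0.5
        assert (out["group"] == HIGH).sum() == 2

    def test_heavily_tied_scores_split_unevenly(self):
        # 100 patients on a 3-level score; median ties all go low
        scores = pd.Series([0.0] * 40 + [1.0] * 35 + [2.0] * 25,
                           index=[f"P{i}" for i in range(100)])
        out = stratify(scores)
        assert out["cutoff"].iloc[0] == 1.0
        assert (out["group"] == HIGH).sum() == 25
        assert (out["group"] == LOW).sum() == 75

    def test_monotone_transform_preserves_groups(self, rng):
        scores = pd.Series(rng.normal(size=31), index=[f"P{i}" for i in range(31)])
        a = stratify(scores)["group"]
        b = stratify(np.exp(scores) * 3 + 1)["group"]
        assert (a == b).all()

    def test_degenerate_scores_rejected(self):
        with pytest.raises(DegenerateStratificationError):
            stratify(pd.Series([1.0, 1.0, 1.0]))

    def test_roc_optimal_rule(self, survival_small):
        surv, clin = survival_small
        pm = encode_pairs(surv, ["LNC0001", "LNC0002", "LNC0003", "LNC0004"])
        scores = risk_score(
            RiskModel(["LNC0001|LNC0002", "LNC0003|LNC0004"], [0.7, 0.4]), pm
        )
        out = stratify(scores, rule="roc_optimal", horizon=24.0, surv=clin)
        assert set(out["group"]) == {HIGH, LOW}
        assert out["cutoff_rule"].iloc[0] == "roc_optimal"


class TestKaplanMeierLogrank:
    def test_hand_computed_product_limit(self):
        # 6 subjects: events at 1,2,4,6; censored at 3,5
        clin = no_censoring_clinical([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        assign = pd.DataFrame(
            {"group": ["g"] * 6, "riskscore": 0.0}, index=clin.samples
        )
        assign.loc[clin.samples[0], "group"] = "h"  # second group for the test
        # use a single-group KM via the curves dict
        curves, _, _ = km_logrank(
            pd.DataFrame({"group": ["a", "a", "a", "a", "a", "b"]},
                         index=clin.samples),
            clin,
        )
        km_a = curves["a"].set_index("time")["survival"]
        # manual product-limit on subjects 1..5: events 1,2,4; censor 3,5
        assert km_a.loc[1.0] == pytest.approx(4 / 5)
        assert km_a.loc[2.0] == pytest.approx(4 / 5 * 3 / 4)
        assert km_a.loc[4.0] == pytest.approx(4 / 5 * 3 / 4 * 1 / 2)

    def test_km_equals_empirical_without_censoring(self, rng):
        t = rng.exponential(10, 40)
        clin = no_censoring_clinical(t)
        assign = pd.DataFrame({"group": ["a"] * 20 + ["b"] * 20},
                              index=clin.samples)
        curves, _, _ = km_logrank(assign, clin)
        ta = np.sort(t[:20])
        km = curves["a"].set_index("time")["survival"]
        for k, ti in enumerate(ta):
            assert km.loc[ti] == pytest.approx(1 - (k + 1) / 20)

    def test_identical_groups_give_zero_statistic(self, rng):
        t = rng.exponential(10, 30)
        tt = np.concatenate([t, t])
        clin = no_censoring_clinical(tt)
        assign = pd.DataFrame({"group": ["a"] * 30 + ["b"] * 30},
                              index=clin.samples)
        _, chi, p = km_logrank(assign, clin)
        assert chi == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self, rng):
        clin = no_censoring_clinical(rng.exponential(10, 10))
        assign = pd.DataFrame({"group": ["a"] * 10}, index=clin.samples)
        with pytest.raises(ValidationError):
            km_logrank(assign, clin)


class TestTimeROC:
    def test_equals_mann_whitney_auc_without_censoring(self, rng):
        t = rng.exponential(20, 80)
        scores = pd.Series(rng.normal(size=80) + 0.05 * (30 - t),
                           index=[f"P{i}" for i in range(80)])
        clin = no_censoring_clinical(t, prefix="P")
        h = float(np.median(t))
        cases = scores[t <= h].to_numpy()
        controls = scores[t > h].to_numpy()
        u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
        auc_mw = u / (len(cases) * len(controls))
        for estimator in ("km", "ipcw"):
            roc = time_roc(scores, clin, h, estimator=estimator)
            assert roc.auc == pytest.approx(auc_mw, abs=1e-9)

    def test_null_scores_auc_near_half(self):
        aucs = []
        for seed in range(40):
            rg = np.random.default_rng(4000 + seed)
            t = rg.exponential(20, 60)
            e = (rg.random(60) < 0.7).astype(int)
            clin = no_censoring_clinical(t, e)
            scores = pd.Series(rg.normal(size=60), index=clin.samples)
            aucs.append(time_roc(scores, clin, 15.0, estimator="ipcw").auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.04)

    def test_auc_grows_with_effect_size(self):
        aucs = {}
        for beta in (0.0, 0.7, 1.4):
            cfg = small_sim_config(
                seed=5, n_samples_survival=600, n_linked_lnc=0, n_de_lnc=0,
                pair_betas={"LNC0001|LNC0002": beta},
            )
            surv, clin = generate_survival_cohort(cfg)
            pm = encode_pairs(surv, ["LNC0001", "LNC0002"])
            scores = risk_score(RiskModel(["LNC0001|LNC0002"], [1.0]), pm)
            scores = scores + pd.Series(
                np.random.default_rng(1).normal(0, 1e-6, len(scores)),
                index=scores.index,
            )  # break exact ties so stratification-free AUC is defined
            aucs[beta] = time_roc(scores, clin, 24.0).auc
        assert 0.48 < aucs[0.0] < 0.56
        assert aucs[0.0] < aucs[0.7] < aucs[1.4]

    def test_auc_invariant_under_monotone_transform(self, rng):
        t = rng.exponential(20, 50)
        e = (rng.random(50) < 0.6).astype(int)
        clin = no_censoring_clinical(t, e)
        scores = pd.Series(rng.normal(size=50), index=clin.samples)
        a = time_roc(scores, clin, 15.0).auc
        b = time_roc(np.exp(scores * 2) + 3, clin, 15.0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_horizon_validation(self, rng):
        clin = no_censoring_clinical(rng.exponential(20, 20))
        scores = pd.Series(rng.normal(size=20), index=clin.samples)
        with pytest.raises(ValidationError):
            time_roc(scores, clin, 1e9)


class TestCoxClinical:
    def test_confounded_covariate_shifts_between_models(self):
        cfg = small_sim_config(
            seed=3, n_samples_survival=1200, n_linked_lnc=0, n_de_lnc=0,
            confounding=1.5,
            pair_betas={"LNC0001|LNC0002": 0.8},
        )
        surv, clin = generate_survival_cohort(cfg)
        pm = encode_pairs(surv, ["LNC0001", "LNC0002"])
        scores = risk_score(RiskModel(["LNC0001|LNC0002"], [0.8]), pm)
        fits = cox_clinical(clin, scores)
        uni = {f.variable: f.beta for f in fits["univariate"]}
        multi = {f.variable: f.beta for f in fits["multivariate"]}
        age_key = [k for k in uni if k.startswith("age")][0]
        assert abs(uni[age_key] - multi[age_key]) > 0.05
        assert abs(uni["riskscore"] - multi["riskscore"]) > 0.02

    def test_riskscore_coefficient_recovered(self):
        cfg = small_sim_config(
            seed=6, n_samples_survival=2000, n_linked_lnc=0, n_de_lnc=0,
            pair_betas={"LNC0001|LNC0002": 0.7},
        )
        surv, clin = generate_survival_cohort(cfg)
        pm = encode_pairs(surv, ["LNC0001", "LNC0002"])
        scores = risk_score(RiskModel(["LNC0001|LNC0002"], [1.0]), pm)
        fits = cox_clinical(clin, scores)
        multi = {f.variable: f.beta for f in fits["multivariate"]}
        assert multi["riskscore"] == pytest.approx(0.7, abs=0.1)

    def test_constant_covariate_rejected(self, survival_small):
        surv, clin = survival_small
        data = clin.data.copy()
        data["age"] = 50.0  # everyone under the dichotomization cut
        clin2 = ClinicalTable(data)
        scores = pd.Series(
            np.random.default_rng(0).normal(size=len(data)), index=data.index
        )
        with pytest.raises(DegeneratePredictorError):
            cox_clinical(clin2, scores)
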