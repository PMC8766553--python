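"""Two-stage MR, bootstrap, exclusion restriction, strata, heterogeneity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit._glm import FitError, ols_fit
from mrkit.onesample import (bootstrap_ci, exclusion_restriction_test,
                             heterogeneity_test, observational_association,
                             stratified_mr, two_stage_mr)
from mrkit.synth import simulate_cohort
from tests.conftest import cohort_grs, make_config


def _arrays(cohort, cfg):
    ph = cohort.phenotypes
    return (ph["exposure"].to_numpy(), cohort_grs(cohort, cfg),
            ph["case"].to_numpy(float), ph["age"].to_numpy(float))


class TestObservational:
    def test_null(self, null_cohort):
        cfg, cohort = null_cohort
        expo, _, case, age = _arrays(cohort, cfg)
        fit = observational_association(expo, case, age)
        assert abs(fit.log_or_per_sd) < 3 * fit.se
        assert fit.ci_low <= fit.odds_ratio <= fit.ci_high

    def test_confounded_or_above_one(self, confounded_null_cohort):
        cfg, cohort = confounded_null_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        obs = observational_association(expo, case, age)
        mr = two_stage_mr(expo, grs, case, age)
        # theta=0 with positive confounding: observational OR departs from 1,
        # the genetically instrumented estimate does not
        assert obs.log_or_per_sd > 3 * obs.se
        assert abs(mr.log_or_per_sd) < 3 * mr.se

    def test_per_raw_unit_phrasing(self, null_cohort):
        cfg, cohort = null_cohort
        expo, _, case, age = _arrays(cohort, cfg)
        fit = observational_association(expo, case, age)
        fit.log_or_per_sd = float(np.log(0.70))
        assert fit.per_raw_units(5.14) == "0.70 per 5.14"


class TestTwoStage:
    def test_null_recovery(self, null_cohort):
        cfg, cohort = null_cohort
        fit = two_stage_mr(*_arrays(cohort, cfg))
        assert abs(fit.log_or_per_sd) < 3 * fit.se
        assert fit.diagnostics["stage1_f"] > 10

    def test_effect_recovery(self, causal_cohort):
        cfg, cohort = causal_cohort
        fit = two_stage_mr(*_arrays(cohort, cfg))
        assert fit.log_or_per_sd == pytest.approx(-0.3, abs=3 * fit.se)

    def test_zero_cases_errors(self, null_cohort):
        cfg, cohort = null_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        with pytest.raises(FitError, match="no cases"):
            two_stage_mr(expo, grs, np.zeros_like(case), age)

    def test_weak_instrument_warns(self):
        rng = np.random.default_rng(2)
        n = 2000
        grs = rng.standard_normal(n)
        expo = 0.01 * grs + rng.standard_normal(n)
        case = (rng.random(n) < 0.1).astype(float)
        age = rng.integers(40, 70, n).astype(float)
        with pytest.warns(UserWarning, match="weak instrument"):
            fit = two_stage_mr(expo, grs, case, age)
        assert fit.diagnostics.get("weak_instrument")

    def test_linear_limit_equals_wald_ratio(self):
        # continuous outcome, identity link: the two-stage coefficient equals
        # cov(Y, GRS) / cov(X, GRS)
        rng = np.random.default_rng(3)
        n = 500
        grs = rng.standard_normal(n)
        x = 0.5 * grs + rng.standard_normal(n)
        y = -0.3 * x + rng.standard_normal(n)
        s1, _, _, _ = ols_fit(np.column_stack([np.ones(n), grs]), x)
        fitted = s1[0] + s1[1] * grs
        s2, _, _, _ = ols_fit(np.column_stack([np.ones(n), fitted]), y)
        wald = np.cov(y, grs)[0, 1] / np.cov(x, grs)[0, 1]
        assert s2[1] == pytest.approx(wald, abs=1e-8)


class TestBootstrap:
    def test_deterministic(self, null_cohort):
        cfg, cohort = null_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        ci1 = bootstrap_ci(expo, grs, case, age, reps=150, seed=9)
        ci2 = bootstrap_ci(expo, grs, case, age, reps=150, seed=9)
        assert ci1 == ci2

    def test_contains_point_estimate(self, null_cohort):
        cfg, cohort = null_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        fit = two_stage_mr(expo, grs, case, age)
        lo, hi = bootstrap_ci(expo, grs, case, age, reps=300, seed=1)
        assert lo < fit.odds_ratio < hi

    def test_reps_guard(self, null_cohort):
        cfg, cohort = null_cohort
        with pytest.raises(ValueError, match="reps"):
            bootstrap_ci(*_arrays(cohort, cfg), reps=50, seed=0)

    def test_stabilises_with_reps(self, null_cohort):
        # endpoints at 500 vs 2000 reps differ by < 10% of interval width
        cfg, cohort = null_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        lo1, hi1 = bootstrap_ci(expo, grs, case, age, reps=500, seed=2)
        lo2, hi2 = bootstrap_ci(expo, grs, case, age, reps=2000, seed=3)
        width = hi2 - lo2
        assert abs(lo1 - lo2) < 0.1 * width
        assert abs(hi1 - hi2) < 0.1 * width


class TestExclusionRestriction:
    def test_no_pleiotropy_null(self, causal_cohort):
        cfg, cohort = causal_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        coef, se, p = exclusion_restriction_test(case, grs, expo, age)
        assert abs(coef) < 3.5 * se

    def test_pleiotropy_detected(self):
        cfg = make_config(
            n_individuals=50000, theta=0.0, pleiotropy=[0.15] * 10,
            baseline_logit=-3.0, seed=29)
        cohort = simulate_cohort(cfg)
        expo, grs, case, age = _arrays(cohort, cfg)
        coef, se, p = exclusion_restriction_test(case, grs, expo, age)
        assert p < 1e-4

    def test_constant_grs_errors(self, null_cohort):
        cfg, cohort = null_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        with pytest.raises(FitError, match="constant GRS"):
            exclusion_restriction_test(case, np.ones_like(grs), expo, age)


class TestStratified:
    def test_homogeneous_truth(self):
        cfg = make_config(
            n_individuals=60000, theta=-0.3, baseline_logit=-3.0,
            stratum_spec={"a": 1.0, "b": 1.0}, seed=37)
        cohort = simulate_cohort(cfg)
        expo, grs, case, age = _arrays(cohort, cfg)
        fits = stratified_mr(expo, grs, case, age,
                             cohort.phenotypes["stratum"])
        assert set(fits) == {"a", "b"}
        het = heterogeneity_test([f.log_or_per_sd for f in fits.values()],
                                 [f.se for f in fits.values()])
        assert het.p > 0.01

    def test_modified_effect_detected(self):
        cfg = make_config(
            n_individuals=100000, theta=-0.25, mafs=[0.3] * 20,
            snp_effects=[0.15] * 20, baseline_logit=-2.5,
            stratum_spec={"lo": 0.0, "hi": 3.0}, seed=39)
        cohort = simulate_cohort(cfg)
        expo, grs, case, age = _arrays(cohort, cfg)
        fits = stratified_mr(expo, grs, case, age,
                             cohort.phenotypes["stratum"])
        het = heterogeneity_test([f.log_or_per_sd for f in fits.values()],
                                 [f.se for f in fits.values()])
        assert het.p < 0.05
        assert fits["hi"].log_or_per_sd < fits["lo"].log_or_per_sd

    def test_single_stratum_errors(self, null_cohort):
        cfg, cohort = null_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        with pytest.raises(FitError, match="at least 2"):
            stratified_mr(expo, grs, case, age,
                          np.full(cohort.n, "only", dtype=object))

    def test_unknown_dropped_and_zero_case_skipped(self, null_cohort):
        cfg, cohort = null_cohort
        expo, grs, case, age = _arrays(cohort, cfg)
        labels = np.array(["a", "b", "unknown"], dtype=object)[
            np.arange(cohort.n) % 3]
        case2 = case.copy()
        case2[labels == "unknown"] = 1.0  # should never be seen
        fits = stratified_mr(expo, grs, case2, age, labels)
        assert "unknown" not in fits


class TestHeterogeneity:
    def test_identical_estimates(self):
        res = heterogeneity_test([0.4, 0.4], [0.1, 0.1])
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.i_squared == 0.0
        assert res.p == pytest.approx(1.0)

    def test_worked_example(self):
        # weights 100 each, pooled 0.4, Q = 100*0.04 + 100*0.04 = 8
        res = heterogeneity_test([0.2, 0.6], [0.1, 0.1])
        assert res.Q == pytest.approx(8.0, abs=1e-12)
        assert res.df == 1
        assert res.i_squared == pytest.approx(87.5, abs=1e-10)

    def test_three_estimate_brute_force(self):
        est = np.array([0.1, 0.15, 0.9])
        se = np.array([0.2, 0.2, 0.2])
        w = 1 / se**2
        pooled = (w * est).sum() / w.sum()
        q_brute = float((w * (est - pooled) ** 2).sum())
        res = heterogeneity_test(est, se)
        assert res.Q == pytest.approx(q_brute, abs=1e-12)

    def test_guards(self):
        with pytest.raises(FitError, match=">= 2"):
            heterogeneity_test([0.1], [0.1])
        with pytest.raises(FitError, match="positive"):
            heterogeneity_test([0.1, 0.2], [0.1, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-5, 5),
           st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 2)),
                    min_size=2, max_size=8))
    def test_shift_invariance(self, shift, pairs):
        est = np.array([p[0] for p in pairs])
        se = np.array([p[1] for p in pairs])
        base = heterogeneity_test(est, se)
        shifted = heterogeneity_test(est + shift, se)
        assert shifted.Q == pytest.approx(base.Q, abs=1e-6)
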