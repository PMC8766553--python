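"""Harmonisation, Wald/IVW/Egger/MVMR estimators vs normal-equation oracles."""

import numpy as np
import pandas as pd
import pytest

from mrkit._glm import FitError
from mrkit.twosample import (HarmonisedStudy, egger, harmonise, ivw, mvmr,
                             wald_ratio)


def _stats(rows):
    return pd.DataFrame(rows, columns=[
        "snp", "effect_allele", "other_allele", "eaf", "beta", "se"])


def _study(bx, by, se_y, se_x=None):
    k = len(bx)
    return HarmonisedStudy(table=pd.DataFrame({
        "snp": [f"rs{i}" for i in range(k)],
        "bx": bx, "se_x": se_x if se_x is not None else [0.01] * k,
        "by": by, "se_y": se_y,
    }))


def _random_study(rng, k=10):
    bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
    se_y = rng.uniform(0.01, 0.05, k)
    by = 0.5 * bx + rng.normal(0, se_y)
    return _study(bx, by, se_y)


def wls_oracle(X, y, w):
    """Independently coded weighted-least-squares normal equations."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    W = np.diag(np.asarray(w, float))
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ np.asarray(y, float))
    resid = y - X @ beta
    ssr = float(resid @ W @ resid)
    cov = np.linalg.inv(X.T @ W @ X)
    return beta, cov, ssr


class TestHarmonise:
    def test_identity(self):
        e = _stats([("rs1", "A", "G", 0.3, 0.2, 0.01)])
        o = _stats([("rs1", "A", "G", 0.3, -0.06, 0.02)])
        h = harmonise(e, o)
        assert h.table.loc[0, "by"] == pytest.approx(-0.06)
        assert not h.table.loc[0, "flipped"]

    def test_swapped_alleles_negate_by(self):
        e = _stats([("rs1", "A", "G", 0.3, 0.2, 0.01)])
        o = _stats([("rs1", "G", "A", 0.7, -0.06, 0.02)])
        h = harmonise(e, o)
        assert h.table.loc[0, "by"] == pytest.approx(0.06)
        assert h.table.loc[0, "flipped"]

    def test_palindromic_half_dropped(self):
        e = _stats([("rs1", "A", "T", 0.50, 0.2, 0.01),
                    ("rs2", "A", "G", 0.3, 0.1, 0.01)])
        o = _stats([("rs1", "A", "T", 0.50, 0.1, 0.02),
                    ("rs2", "A", "G", 0.3, 0.1, 0.02)])
        h = harmonise(e, o)
        assert list(h.table["snp"]) == ["rs2"]
        assert h.drop_reasons["unresolvable"] == 1

    def test_absent_from_outcome_counted(self):
        e = _stats([("rs1", "A", "G", 0.3, 0.2, 0.01),
                    ("rs2", "C", "T", 0.2, 0.1, 0.01)])
        o = _stats([("rs2", "C", "T", 0.2, 0.1, 0.02)])
        h = harmonise(e, o)
        assert h.drop_reasons["absent_from_outcome"] == 1

    def test_zero_overlap_errors(self):
        e = _stats([("rs1", "A", "G", 0.3, 0.2, 0.01)])
        o = _stats([("rs9", "A", "G", 0.3, 0.2, 0.02)])
        with pytest.raises(FitError, match="no overlapping"):
            harmonise(e, o)


class TestWaldRatio:
    def test_arithmetic(self):
        est, se = wald_ratio(0.2, -0.06, 0.02)
        assert est == pytest.approx(-0.3)
        assert se == pytest.approx(0.1)

    def test_zero_by(self):
        est, se = wald_ratio(0.2, 0.0, 0.02)
        assert est == 0.0 and se == pytest.approx(0.1)

    def test_zero_bx_errors(self):
        with pytest.raises(FitError, match="Wald ratio"):
            wald_ratio(0.0, 0.1, 0.02)


class TestIVW:
    def test_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3])
        fit = ivw(_study(bx, 0.5 * bx, [0.01] * 3))
        assert fit.log_or_per_sd == pytest.approx(0.5, abs=1e-12)
        assert fit.diagnostics["Q"] == pytest.approx(0.0, abs=1e-20)
        assert fit.se == pytest.approx(fit.diagnostics["se_fixed_effect"])

    def test_wls_oracle_equivalence(self):
        study = _study([0.1, 0.2, 0.3], [0.03, 0.02, 0.09], [0.01] * 3)
        fit = ivw(study)
        t = study.table
        beta, cov, ssr = wls_oracle(t["bx"], t["by"], 1 / t["se_y"] ** 2)
        scale = max(1.0, np.sqrt(ssr / 2))
        assert fit.log_or_per_sd == pytest.approx(beta[0], abs=1e-10)
        assert fit.se == pytest.approx(np.sqrt(cov[0, 0]) * scale, abs=1e-10)

    def test_k1_errors(self):
        with pytest.raises(FitError, match="at least 2"):
            ivw(_study([0.1], [0.03], [0.01]))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        s = _random_study(rng)
        base = ivw(s).log_or_per_sd
        t = s.table.copy()
        t["bx"] *= 3.0
        assert ivw(HarmonisedStudy(t)).log_or_per_sd == pytest.approx(
            base / 3.0, abs=1e-12)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(9)
        s = _random_study(rng)
        base = ivw(s)
        t = s.table.copy()
        t.loc[::2, ["bx", "by"]] *= -1.0
        flipped = ivw(HarmonisedStudy(t))
        assert flipped.log_or_per_sd == pytest.approx(base.log_or_per_sd,
                                                      abs=1e-12)
        assert flipped.se == pytest.approx(base.se, abs=1e-12)

    def test_mre_se_floor(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            s = _random_study(rng)
            fit = ivw(s)
            assert fit.se >= fit.diagnostics["se_fixed_effect"] - 1e-15


class TestEgger:
    def test_exact_line_with_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 0.8 * bx
        fit = egger(_study(bx, by, [0.01] * 4))
        assert fit.slope == pytest.approx(0.8, abs=1e-10)
        assert fit.intercept == pytest.approx(0.05, abs=1e-10)
        assert fit.residual_scale == pytest.approx(1.0)  # floored

    def test_reorientation_rule(self):
        # flipping a variant's (bx, by) jointly must not change the fit
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = 0.05 + 0.8 * bx
        by[1] = -(0.05 + 0.8 * 0.2)  # directional pleiotropy on the true scale
        fit = egger(_study(bx, by, [0.01] * 4))
        t2 = _study(-bx, -by, [0.01] * 4)
        fit2 = egger(t2)
        assert fit.slope == pytest.approx(fit2.slope, abs=1e-12)
        assert fit.intercept == pytest.approx(fit2.intercept, abs=1e-12)

    def test_wls_oracle_equivalence(self):
        rng = np.random.default_rng(11)
        s = _random_study(rng, k=8)
        fit = egger(s)
        t = s.table.copy()
        neg = t["bx"] < 0
        t.loc[neg, ["bx", "by"]] *= -1.0
        X = np.column_stack([np.ones(len(t)), t["bx"]])
        beta, cov, ssr = wls_oracle(X, t["by"].to_numpy(), 1 / t["se_y"] ** 2)
        scale = max(1.0, np.sqrt(ssr / (len(t) - 2)))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.slope_se == pytest.approx(np.sqrt(cov[1, 1]) * scale,
                                             abs=1e-10)

    def test_k2_errors(self):
        with pytest.raises(FitError, match="at least 3"):
            egger(_study([0.1, 0.2], [0.03, 0.05], [0.01, 0.01]))


class TestMVMR:
    def _pair_of_studies(self, rng, theta1=-0.3, theta2=0.0, k=30):
        bx1 = rng.uniform(0.05, 0.3, k)
        bx2 = 0.5 * bx1 + rng.uniform(0.02, 0.1, k)  # correlated exposures
        se_y = np.full(k, 0.02)
        by = theta1 * bx1 + theta2 * bx2 + rng.normal(0, se_y)
        s1 = _study(bx1, by, se_y)
        t2 = s1.table.copy()
        t2["bx"] = bx2
        return {"x1": s1, "x2": HarmonisedStudy(t2)}

    def test_recovers_direct_effects(self):
        rng = np.random.default_rng(12)
        ests1, ests2 = [], []
        for _ in range(50):
            res = mvmr(self._pair_of_studies(rng))
            res = res.set_index("exposure")
            ests1.append(res.loc["x1", "estimate"])
            ests2.append(res.loc["x2", "estimate"])
        assert np.mean(ests1) == pytest.approx(-0.3, abs=0.03)
        assert np.mean(ests2) == pytest.approx(0.0, abs=0.03)

    def test_second_exposure_null_reduces_to_ivw(self, caplog):
        rng = np.random.default_rng(13)
        studies = self._pair_of_studies(rng)
        t2 = studies["x2"].table.copy()
        t2["bx"] = 0.0
        with caplog.at_level("WARNING"):
            res = mvmr({"x1": studies["x1"],
                        "x2_zero": HarmonisedStudy(t2)})
        assert "all-zero" in caplog.text
        uni = ivw(studies["x1"])
        assert res.set_index("exposure").loc["x1", "estimate"] == pytest.approx(
            uni.log_or_per_sd, abs=1e-12)

    def test_rank_deficiency_errors(self):
        rng = np.random.default_rng(14)
        studies = self._pair_of_studies(rng)
        t2 = studies["x1"].table.copy()  # exact copy => collinear
        with pytest.raises(FitError, match="collinear"):
            mvmr({"x1": studies["x1"], "x1_copy": HarmonisedStudy(t2)})

    def test_wls_oracle_equivalence(self):
        rng = np.random.default_rng(15)
        studies = self._pair_of_studies(rng, k=12)
        res = mvmr(studies).set_index("exposure")
        t1 = studies["x1"].table.set_index("snp")
        t2 = studies["x2"].table.set_index("snp")
        B = np.column_stack([t1["bx"], t2["bx"]])
        beta, cov, ssr = wls_oracle(B, t1["by"].to_numpy(),
                                    1 / t1["se_y"] ** 2)
        scale = max(1.0, np.sqrt(ssr / (len(t1) - 2)))
        assert res.loc["x1", "estimate"] == pytest.approx(beta[0], abs=1e-10)
        assert res.loc["x2", "estimate"] == pytest.approx(beta[1], abs=1e-10)
        assert res.loc["x1", "se"] == pytest.approx(
            np.sqrt(cov[0, 0]) * scale, abs=1e-10)

    def test_duplicate_variants_deduplicated(self, caplog):
        rng = np.random.default_rng(16)
        studies = self._pair_of_studies(rng)
        t1 = studies["x1"].table
        dup = pd.concat([t1, t1.iloc[[0]]], ignore_index=True)
        with caplog.at_level("WARNING"):
            res = mvmr({"x1": HarmonisedStudy(dup), "x2": studies["x2"]})
        assert "de-duplicated" in caplog.text
        assert res["k_variants"].iloc[0] == len(t1)

    def test_single_exposure_errors(self):
        rng = np.random.default_rng(17)
        studies = self._pair_of_studies(rng)
        with pytest.raises(FitError, match="at least 2"):
            mvmr({"x1": studies["x1"]})


class TestConvergence:
    def test_ivw_and_egger_converge_to_theta(self):
        # no pleiotropy: as per-variant SEs shrink, both estimators approach
        # the generative slope
        rng = np.random.default_rng(18)
        k = 50
        bx = rng.uniform(0.05, 0.3, k)
        for se_scale, tol in [(0.02, 0.05), (0.0002, 0.0005)]:
            se_y = np.full(k, se_scale)
            by = -0.3 * bx + rng.normal(0, se_y)
            s = _study(bx, by, se_y)
            assert ivw(s).log_or_per_sd == pytest.approx(-0.3, abs=tol)
            assert egger(s).slope == pytest.approx(-0.3, abs=3 * tol)
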