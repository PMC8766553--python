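"""One-sample MR on individual-level data.

Observational logistic associations, the two-stage estimator (linear first
stage on the GRS, logistic second stage on fitted exposure values, adjusted
for age), percentile-bootstrap confidence intervals, the exclusion-restriction
check, stratified estimates and a fixed-effect chi-squared heterogeneity test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mrkit._glm import FitError, logistic_fit, ols_fit

log = logging.getLogger(__name__)

WEAK_INSTRUMENT_F = 10.0


@dataclass
class MRFit:
    """A causal (or observational) estimate on the log-odds-per-SD scale."""

    log_or_per_sd: float
    se: float
    ci_low: float   # OR scale
    ci_high: float  # OR scale
    p: float
    method: str
    n_cases: int
    n_controls: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or_per_sd))

    def per_raw_units(self, sd: float) -> str:
        """Phrase the per-SD OR in raw exposure units, e.g. '0.70 per 5.14 kg/m^2'."""
        return f"{self.odds_ratio:.2f} per {sd:g}"


@dataclass
class HeterogeneityResult:
    """Cochran Q heterogeneity across stratum estimates."""

    Q: float
    df: int
    p: float
    i_squared: float  # percentage


def _wald_fit(beta: float, se: float, method: str, n_cases: int,
              n_controls: int, diagnostics: dict | None = None) -> MRFit:
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    half = stats.norm.ppf(0.975) * se
    return MRFit(
        log_or_per_sd=float(beta), se=float(se),
        ci_low=float(np.exp(beta - half)), ci_high=float(np.exp(beta + half)),
        p=float(p), method=method, n_cases=int(n_cases),
        n_controls=int(n_controls), diagnostics=diagnostics or {},
    )


def _complete(*arrays):
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= np.isfinite(np.asarray(a, dtype=float))
    return [np.asarray(a, dtype=float)[mask] for a in arrays]


def observational_association(exposure, case_status, age) -> MRFit:
    """Logistic regression of case status on exposure, adjusted for baseline age."""
    exposure, case, age = _complete(exposure, case_status, age)
    X = np.column_stack([np.ones_like(exposure), exposure, age])
    beta, se, _ = logistic_fit(X, case)
    return _wald_fit(beta[1], se[1], "observational", case.sum(),
                     len(case) - case.sum())


def _two_stage_core(exposure, grs, case, age, start=None):
    """Both stages on complete-case arrays; returns (beta, se, stage1 slope)."""
    s1_beta, _, _, _ = ols_fit(np.column_stack([np.ones_like(grs), grs]), exposure)
    fitted = s1_beta[0] + s1_beta[1] * grs
    X2 = np.column_stack([np.ones_like(fitted), fitted, age])
    b2, se2, _ = logistic_fit(X2, case, start=start)
    return b2, se2, s1_beta[1]


def two_stage_mr(exposure, grs, case_status, age) -> MRFit:
    """Two-stage one-sample MR.

    Stage 1 regresses the exposure on the GRS; stage 2 is a logistic
    regression of the outcome on the stage-1 fitted values, adjusted for
    age. An F below 10 tags the fit as weak-instrument (warning, not error).
    """
    exposure, grs, case, age = _complete(exposure, grs, case_status, age)
    if case.sum() == 0:
        raise FitError("no cases in analysis sample")
    from mrkit.instruments import instrument_strength

    strength = instrument_strength(grs, exposure)
    b2, se2, _ = _two_stage_core(exposure, grs, case, age)
    diagnostics = {
        "stage1_r_squared": strength.r_squared,
        "stage1_f": strength.f_statistic,
    }
    if strength.f_statistic < WEAK_INSTRUMENT_F:
        diagnostics["weak_instrument"] = True
        warnings.warn(
            f"weak instrument: first-stage F = {strength.f_statistic:.2f} < 10",
            stacklevel=2)
    return _wald_fit(b2[1], se2[1], "two-stage", case.sum(),
                     len(case) - case.sum(), diagnostics)


def bootstrap_ci(exposure, grs, case_status, age, reps: int = 10000,
                 seed: int = 0, max_failures: float = 0.05):
    """Percentile bootstrap CI (OR scale) for the two-stage estimate.

    Participants are resampled with replacement and both stages are refitted
    in every replicate. Deterministic given ``seed``. More than
    ``max_failures`` non-converging replicates is an error.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    exposure, grs, case, age = _complete(exposure, grs, case_status, age)
    n = len(case)
    # warm start from the full-sample stage-2 fit
    b_full, _, _ = _two_stage_core(exposure, grs, case, age)
    rng = np.random.default_rng(seed)
    estimates = np.empty(reps)
    failures = 0
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            b2, _, _ = _two_stage_core(exposure[idx], grs[idx], case[idx],
                                       age[idx], start=b_full)
        except FitError:
            estimates[r] = np.nan
            failures += 1
            continue
        estimates[r] = b2[1]
    if failures > max_failures * reps:
        raise FitError(f"{failures}/{reps} bootstrap replicates failed")
    lo, hi = np.nanpercentile(estimates, [2.5, 97.5])
    return float(np.exp(lo)), float(np.exp(hi))


def exclusion_restriction_test(case_status, grs, exposure, age):
    """Regress the outcome on the GRS adjusted for the exposure (and age).

    Under a valid instrument the GRS coefficient is null; association flags
    an exclusion-restriction violation. Returns (coefficient, se, p).
    """
    case, grs, exposure, age = _complete(case_status, grs, exposure, age)
    if np.var(grs) == 0.0:
        raise FitError("constant GRS")
    X = np.column_stack([np.ones_like(grs), grs, exposure, age])
    beta, se, _ = logistic_fit(X, case)
    z = beta[1] / se[1]
    p = 2.0 * stats.norm.sf(abs(z))
    return float(beta[1]), float(se[1]), float(p)


def stratified_mr(exposure, grs, case_status, age, labels,
                  skip_labels=("unknown", "")) -> dict:
    """Two-stage MR per stratum; unknown-stratum participants are dropped.

    Strata with zero cases are skipped with a warning. Fewer than two
    usable strata is an error.
    """
    labels = np.asarray(labels, dtype=object)
    usable = sorted({l for l in labels if l not in skip_labels and l == l})
    if len(usable) < 2:
        raise FitError("stratified MR needs at least 2 non-empty strata")
    exposure = np.asarray(exposure, dtype=float)
    grs = np.asarray(grs, dtype=float)
    case = np.asarray(case_status, dtype=float)
    age = np.asarray(age, dtype=float)
    fits = {}
    for lab in usable:
        m = labels == lab
        if np.nansum(case[m]) == 0:
            log.warning("stratum %r has zero cases; skipped", lab)
            continue
        try:
            fits[lab] = two_stage_mr(exposure[m], grs[m], case[m], age[m])
        except FitError as exc:
            log.warning("stratum %r skipped: %s", lab, exc)
    if len(fits) < 2:
        raise FitError("fewer than 2 strata produced estimates")
    return fits


def heterogeneity_test(estimates, ses) -> HeterogeneityResult:
    """Fixed-effect Cochran Q test across estimates with I^2.

    Weights are 1/SE^2; Q is the weighted squared deviation from the pooled
    mean, referred to chi-squared with k-1 df; I^2 = max(0, (Q-df)/Q)*100.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size < 2:
        raise FitError("heterogeneity test needs >= 2 estimates")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise FitError("all SEs must be positive and finite")
    w = 1.0 / se**2
    pooled = float(np.sum(w * est) / np.sum(w))
    Q = float(np.sum(w * (est - pooled) ** 2))
    df = int(est.size - 1)
    p = float(stats.chi2.sf(Q, df))
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, p=p, i_squared=float(i2))
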