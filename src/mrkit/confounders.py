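"""Stepwise confounder-attenuation search.

Screens candidate covariates for association with both the exposure and the
outcome, then greedily adds the covariate that most shrinks the absolute
log-odds ratio of the exposure, stopping when no candidate improves it
beyond a tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrkit._glm import FitError, logistic_fit, simple_slope

log = logging.getLogger(__name__)

MIN_NONMISSING = 1000


@dataclass
class SearchTrace:
    """Record of a stepwise attenuation run.

    ``steps`` columns: step, covariate, ln_or, se, n, reduction. |ln_or| is
    non-increasing along the trace by construction of the acceptance rule.
    """

    initial_log_or: float
    initial_se: float
    initial_n: int
    steps: pd.DataFrame
    stop_reason: str
    selected: list = field(default_factory=list)


def _expand_categoricals(table: pd.DataFrame, candidates) -> pd.DataFrame:
    """One binary indicator column per level of each categorical candidate."""
    out = {}
    for col in candidates:
        s = table[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = pd.to_numeric(s, errors="coerce")
            continue
        s = s.astype(object).replace("", np.nan)
        for level in sorted(x for x in s.dropna().unique()):
            out[f"{col}={level}"] = (s == level).astype(float).where(s.notna())
    return pd.DataFrame(out, index=table.index)


def _logistic_p(y, x, age):
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(age)
    X = np.column_stack([np.ones(mask.sum()), x[mask], age[mask]])
    beta, se, _ = logistic_fit(X, y[mask])
    from scipy import stats
    return 2.0 * stats.norm.sf(abs(beta[1] / se[1]))


def screen_candidates(
    table: pd.DataFrame,
    exposure_col: str,
    outcome_col: str,
    candidates,
    age_col: str = "age",
    alpha: float = 0.05,
    min_nonmissing: int = MIN_NONMISSING,
):
    """Eligible covariates: >1000 non-missing, associated with both axes.

    Association is tested by simple linear regression against the exposure
    and by age-adjusted logistic regression against the outcome, both at
    p < alpha. Categorical candidates are expanded to one binary variable
    per level before screening. Returns (eligible names, report table).
    """
    expanded = _expand_categoricals(table, candidates)
    exposure = pd.to_numeric(table[exposure_col], errors="coerce").to_numpy(float)
    outcome = pd.to_numeric(table[outcome_col], errors="coerce").to_numpy(float)
    age = pd.to_numeric(table[age_col], errors="coerce").to_numpy(float)

    rows = []
    for name in expanded.columns:
        x = expanded[name].to_numpy(float)
        n_nonmiss = int(np.isfinite(x).sum())
        p_exp = np.nan
        p_out = np.nan
        eligible = False
        if n_nonmiss > min_nonmissing:
            try:
                m = np.isfinite(x) & np.isfinite(exposure)
                _, _, p_exp = simple_slope(x[m], exposure[m])
                p_out = _logistic_p(outcome, x, age)
                eligible = (p_exp < alpha) and (p_out < alpha)
            except FitError as exc:
                log.warning("candidate %s skipped in screen: %s", name, exc)
        rows.append({"candidate": name, "n_nonmissing": n_nonmiss,
                     "p_exposure": p_exp, "p_outcome": p_out,
                     "eligible": eligible})
    report = pd.DataFrame(rows)
    eligible = sorted(report.loc[report["eligible"], "candidate"])
    return eligible, report


def _exposure_lnor(table, exposure_col, outcome_col, age_col, covariates):
    """Fit outcome ~ exposure + age + covariates on complete cases."""
    cols = [exposure_col, age_col] + list(covariates)
    sub = table[[outcome_col] + cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(sub)
    X = np.column_stack([np.ones(n)] + [sub[c].to_numpy(float) for c in cols])
    beta, se, _ = logistic_fit(X, sub[outcome_col].to_numpy(float))
    return float(beta[1]), float(se[1]), n


def stepwise_attenuation(
    table: pd.DataFrame,
    exposure_col: str,
    outcome_col: str,
    candidates,
    age_col: str = "age",
    tolerance: float = 0.01,
) -> SearchTrace:
    """Greedy forward selection minimising |ln(OR)| of the exposure.

    Age is in every model. At each step the remaining candidate giving the
    smallest |ln(OR)| is added if it shrinks |ln(OR)| by more than
    ``tolerance`` (relative). Ties break lexicographically by covariate
    name. Candidates whose model fails to converge are skipped that step.
    Each model is fitted on its own complete cases, with n logged.
    """
    expanded = _expand_categoricals(table, candidates)
    work = pd.concat(
        [table[[exposure_col, outcome_col, age_col]], expanded], axis=1)

    ln0, se0, n0 = _exposure_lnor(work, exposure_col, outcome_col, age_col, [])
    current = abs(ln0)
    remaining = sorted(expanded.columns)
    selected: list[str] = []
    steps = []
    stop_reason = "candidates exhausted"
    if not remaining:
        stop_reason = "no candidates"
    while remaining:
        best = None
        for cand in remaining:  # sorted: ties resolve lexicographically
            try:
                ln, se, n = _exposure_lnor(
                    work, exposure_col, outcome_col, age_col, selected + [cand])
            except FitError as exc:
                log.warning("candidate %s skipped: %s", cand, exc)
                continue
            if best is None or abs(ln) < best[1]:
                best = (cand, abs(ln), ln, se, n)
        if best is None:
            stop_reason = "no fittable candidates"
            break
        cand, best_abs, ln, se, n = best
        reduction = (current - best_abs) / current if current > 0 else 0.0
        if reduction <= tolerance:
            stop_reason = "no candidate reduces |ln(OR)| beyond tolerance"
            break
        selected.append(cand)
        remaining.remove(cand)
        steps.append({"step": len(selected), "covariate": cand, "ln_or": ln,
                      "se": se, "n": n, "reduction": reduction})
        current = best_abs
    return SearchTrace(
        initial_log_or=ln0, initial_se=se0, initial_n=n0,
        steps=pd.DataFrame(
            steps, columns=["step", "covariate", "ln_or", "se", "n", "reduction"]),
        stop_reason=stop_reason, selected=selected,
    )
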