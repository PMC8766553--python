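"""Non-linear MR by the sliding-window method.

Participants are ordered by IV-free exposure residuals (exposure regressed
on the GRS, age, age squared, the leading genetic principal components and
genotyping array), a fixed-size window slides over that order, and a
localized causal estimate is computed per window: the within-window
GRS-outcome log-odds coefficient scaled by the GRS-exposure slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mrkit._glm import FitError, logistic_fit, ols_fit

log = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Sliding-window geometry. Defaults follow the 50,000 / 1,000 convention."""

    window_size: int = 50000
    step_size: int = 1000

    def __post_init__(self) -> None:
        if not (1 <= self.step_size <= self.window_size):
            raise ValueError("need 1 <= step_size <= window_size")


@dataclass
class WindowProfile:
    """Per-window mean exposure and localized causal estimates.

    ``table`` columns: window, start, stop, mean_exposure, estimate, se,
    n_cases. Windows with no cases carry NaN estimates and are flagged.
    """

    table: pd.DataFrame
    spec: WindowSpec
    denominator: str  # "whole-sample" or "per-window"


def iv_free_residuals(exposure, grs, age, pcs=None, array_indicator=None):
    """Residuals of exposure ~ GRS + age + age^2 (+ PC1..4 + array)."""
    exposure = np.asarray(exposure, dtype=float)
    grs = np.asarray(grs, dtype=float)
    age = np.asarray(age, dtype=float)
    cols = [np.ones_like(exposure), grs, age, age**2]
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.ndim == 1:
            pcs = pcs[:, None]
        cols.extend(pcs.T)
    if array_indicator is not None:
        cols.append(np.asarray(array_indicator, dtype=float))
    X = np.column_stack(cols)
    try:
        _, _, resid, _ = ols_fit(X, exposure)
    except FitError as exc:
        raise FitError(f"collinear covariates in residual model: {exc}") from exc
    return resid


def make_windows(n: int, spec: WindowSpec):
    """Index ranges [k*step, k*step + window) over the residual-sorted order."""
    if n < spec.window_size:
        raise FitError(
            f"n={n} smaller than window_size={spec.window_size}; "
            "use a smaller window")
    n_windows = (n - spec.window_size) // spec.step_size + 1
    return [(k * spec.step_size, k * spec.step_size + spec.window_size)
            for k in range(n_windows)]


def window_lace(grs, case_status, age, denominator: float):
    """Localized estimate for one window's arrays.

    Numerator: GRS coefficient from logistic case ~ GRS + age within the
    window. Denominator: a GRS-exposure slope supplied by the caller
    (whole-sample by default, per-window behind a switch). SE by the delta
    method treating the denominator as fixed. Returns (estimate, se);
    (nan, nan) when the window has no cases.
    """
    grs = np.asarray(grs, dtype=float)
    case = np.asarray(case_status, dtype=float)
    age = np.asarray(age, dtype=float)
    if case.sum() == 0:
        return np.nan, np.nan
    if np.var(grs) == 0.0:
        return np.nan, np.nan
    if denominator == 0:
        raise FitError("zero GRS-exposure slope: ratio undefined")
    X = np.column_stack([np.ones_like(grs), grs, age])
    try:
        beta, se, _ = logistic_fit(X, case)
    except FitError:
        return np.nan, np.nan
    return beta[1] / denominator, se[1] / abs(denominator)


def sliding_profile(exposure, grs, case_status, age, spec: WindowSpec,
                    pcs=None, array_indicator=None,
                    per_window_denominator: bool = False) -> WindowProfile:
    """Assemble the full exposure-vs-effect profile.

    Sorting is a stable argsort of the IV-free residuals, so ties keep
    input (participant) order.
    """
    exposure = np.asarray(exposure, dtype=float)
    grs = np.asarray(grs, dtype=float)
    case = np.asarray(case_status, dtype=float)
    age = np.asarray(age, dtype=float)
    resid = iv_free_residuals(exposure, grs, age, pcs, array_indicator)
    order = np.argsort(resid, kind="stable")

    if not per_window_denominator:
        s1, _, _, _ = ols_fit(np.column_stack([np.ones_like(grs), grs]), exposure)
        denom_global = s1[1]

    rows = []
    for widx, (start, stop) in enumerate(make_windows(len(exposure), spec)):
        sel = order[start:stop]
        if per_window_denominator:
            try:
                s1w, _, _, _ = ols_fit(
                    np.column_stack([np.ones(len(sel)), grs[sel]]), exposure[sel])
                denom = s1w[1]
            except FitError:
                denom = 0.0
        else:
            denom = denom_global
        if denom == 0.0:
            est, se = np.nan, np.nan
        else:
            est, se = window_lace(grs[sel], case[sel], age[sel], denom)
        if not np.isfinite(est):
            log.warning("window %d has no usable estimate; flagged", widx)
        rows.append({
            "window": widx, "start": start, "stop": stop,
            "mean_exposure": float(exposure[sel].mean()),
            "estimate": est, "se": se,
            "n_cases": int(case[sel].sum()),
        })
    return WindowProfile(
        table=pd.DataFrame(rows), spec=spec,
        denominator="per-window" if per_window_denominator else "whole-sample",
    )


def plot_profile(profile: WindowProfile, path) -> None:
    """Estimate vs window-mean exposure with a 95% CI band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = profile.table.dropna(subset=["estimate"])
    fig, ax = plt.subplots(figsize=(7, 4.5))
    lo = t["estimate"] - 1.96 * t["se"]
    hi = t["estimate"] + 1.96 * t["se"]
    ax.fill_between(t["mean_exposure"], lo, hi, alpha=0.25, lw=0)
    ax.plot(t["mean_exposure"], t["estimate"], lw=1.5)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("window mean exposure")
    ax.set_ylabel("localized log-OR per SD")
    ax.set_title(f"sliding-window MR ({profile.denominator} denominator)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
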