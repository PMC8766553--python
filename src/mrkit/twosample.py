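"""Summary-data MR: harmonisation, Wald ratio, IVW, MR-Egger, MVMR.

IVW is a weighted regression of outcome betas on exposure betas through the
origin with weights 1/se_y^2 and a multiplicative random-effects SE
(fixed-effect SE inflated by the residual scale, floored at 1). MR-Egger
adds a free intercept — the intercept tests directional pleiotropy — after
reorienting variants so every exposure beta is non-negative. MVMR regresses
outcome betas on the matrix of exposure betas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from mrkit._glm import FitError
from mrkit.instruments import resolve_orientation
from mrkit.onesample import MRFit

log = logging.getLogger(__name__)


@dataclass
class HarmonisedStudy:
    """Allele-aligned per-variant exposure/outcome summary statistics.

    ``table`` columns: snp, bx, se_x, by, se_y, flipped. Drop bookkeeping is
    kept in ``drop_reasons`` (reason -> count).
    """

    table: pd.DataFrame
    drop_reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        required = ["snp", "bx", "se_x", "by", "se_y"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"harmonised table missing columns: {missing}")
        if t[["bx", "by", "se_y"]].isna().any().any():
            raise ValueError("harmonised table has missing bx/by/se_y")
        if (t["se_y"] <= 0).any():
            raise ValueError("se_y must be positive")

    @property
    def k(self) -> int:
        return len(self.table)


@dataclass
class EggerFit:
    """MR-Egger fit: slope is the causal estimate, intercept the pleiotropy test."""

    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_p: float
    k: int
    ci_low: float   # OR scale, slope
    ci_high: float  # OR scale, slope
    residual_scale: float


def harmonise(exposure_stats: pd.DataFrame,
              outcome_stats: pd.DataFrame) -> HarmonisedStudy:
    """Align outcome summary statistics to the exposure's effect alleles.

    Swapped alleles flip the sign of the outcome beta; strand complements
    are tolerated; palindromic variants are kept only when allele
    frequencies on both sides are outside [0.42, 0.58] (and flipped when
    the frequencies disagree in side). Variants absent from the outcome
    study are dropped with a count.
    """
    exp = exposure_stats.set_index("snp")
    out = outcome_stats.set_index("snp")
    drops = {"absent_from_outcome": 0, "unresolvable": 0}
    rows = []
    for snp, e in exp.iterrows():
        if snp not in out.index:
            drops["absent_from_outcome"] += 1
            continue
        o = out.loc[snp]
        orient = resolve_orientation(
            str(e["effect_allele"]), str(e["other_allele"]), e.get("eaf"),
            str(o["effect_allele"]), str(o["other_allele"]), o.get("eaf"),
        )
        if orient is None:
            drops["unresolvable"] += 1
            continue
        rows.append({
            "snp": snp,
            "bx": float(e["beta"]), "se_x": float(e["se"]),
            "by": orient * float(o["beta"]), "se_y": float(o["se"]),
            "flipped": orient == -1,
        })
    for reason, cnt in drops.items():
        if cnt:
            log.warning("harmonisation dropped %d variants (%s)", cnt, reason)
    if not rows:
        raise FitError("no overlapping variants after harmonisation")
    return HarmonisedStudy(table=pd.DataFrame(rows), drop_reasons=drops)


def wald_ratio(bx: float, by: float, se_y: float):
    """Single-variant causal estimate by/bx with first-order SE se_y/|bx|."""
    if bx == 0:
        raise FitError("exposure beta is zero: Wald ratio undefined")
    return by / bx, se_y / abs(bx)


def _mre_scale(ssr: float, dof: int) -> float:
    # multiplicative random effects: residual scale floored at 1 so
    # underdispersion never shrinks the fixed-effect SE
    if dof <= 0:
        return 1.0
    return max(1.0, float(np.sqrt(ssr / dof)))


def ivw(study: HarmonisedStudy) -> MRFit:
    """Inverse-variance-weighted estimate with multiplicative random effects."""
    t = study.table
    if len(t) < 2:
        raise FitError("IVW needs at least 2 variants")
    bx = t["bx"].to_numpy(float)
    by = t["by"].to_numpy(float)
    w = 1.0 / t["se_y"].to_numpy(float) ** 2
    res = sm.WLS(by, bx[:, None], weights=w).fit()
    beta = float(res.params[0])
    se_fe = float(np.sqrt(res.normalized_cov_params[0, 0]))
    scale = _mre_scale(res.ssr, len(t) - 1)
    se = se_fe * scale
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    half = stats.norm.ppf(0.975) * se
    return MRFit(
        log_or_per_sd=beta, se=se,
        ci_low=float(np.exp(beta - half)), ci_high=float(np.exp(beta + half)),
        p=float(p), method="IVW (multiplicative random effects)",
        n_cases=0, n_controls=0,
        diagnostics={"k": len(t), "Q": float(res.ssr), "mre_scale": scale,
                     "se_fixed_effect": se_fe},
    )


def egger(study: HarmonisedStudy) -> EggerFit:
    """MR-Egger regression with intercept-based pleiotropy test.

    Variants are first reoriented so every bx >= 0 (flipping (bx, by)
    jointly), which lets the intercept capture directional pleiotropy.
    SEs use the multiplicative random-effects scale with k-2 df, and
    p-values come from the t distribution with k-2 df.
    """
    t = study.table
    k = len(t)
    if k < 3:
        raise FitError("MR-Egger needs at least 3 variants")
    bx = t["bx"].to_numpy(float).copy()
    by = t["by"].to_numpy(float).copy()
    neg = bx < 0
    bx[neg] *= -1.0
    by[neg] *= -1.0
    w = 1.0 / t["se_y"].to_numpy(float) ** 2
    Z = sm.add_constant(bx)
    res = sm.WLS(by, Z, weights=w).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    scale = _mre_scale(res.ssr, k - 2)
    se_fe = np.sqrt(np.diag(res.normalized_cov_params))
    intercept_se, slope_se = float(se_fe[0] * scale), float(se_fe[1] * scale)
    dof = k - 2
    slope_p = 2.0 * stats.t.sf(abs(slope / slope_se), dof)
    intercept_p = 2.0 * stats.t.sf(abs(intercept / intercept_se), dof)
    half = stats.t.ppf(0.975, dof) * slope_se
    return EggerFit(
        slope=slope, slope_se=slope_se, slope_p=float(slope_p),
        intercept=intercept, intercept_se=intercept_se,
        intercept_p=float(intercept_p), k=k,
        ci_low=float(np.exp(slope - half)), ci_high=float(np.exp(slope + half)),
        residual_scale=scale,
    )


def mvmr(studies: dict) -> pd.DataFrame:
    """Multivariable MR over harmonised studies sharing one outcome.

    ``studies`` maps exposure name -> HarmonisedStudy. The instrument set is
    the union of variants, de-duplicated by variant identity (no LD
    pruning — flagged in the output); variants missing a beta for any
    exposure are dropped. Outcome betas are regressed on the matrix of
    exposure betas without intercept, weights 1/se_y^2.
    """
    if len(studies) < 2:
        raise FitError("MVMR needs at least 2 exposures")
    names = sorted(studies)
    frames = []
    for name in names:
        t = studies[name].table
        dup = int(t["snp"].duplicated().sum())
        if dup:
            log.warning("MVMR: %d duplicate variant ids in %s de-duplicated",
                        dup, name)
        t = t.drop_duplicates("snp").set_index("snp")
        frames.append(t[["bx"]].rename(columns={"bx": name}))
        frames.append(t[["by", "se_y"]])
    bx_mat = pd.concat([f for f in frames[::2]], axis=1, join="outer")
    outc = pd.concat([f for f in frames[1::2]], axis=0)
    outc = outc[~outc.index.duplicated(keep="first")]
    merged = bx_mat.join(outc, how="inner").dropna()
    # an exposure with no instrument signal at all carries no information
    # and would only make the design singular
    zero = [n for n in names if (merged[n] == 0).all()]
    for n in zero:
        log.warning("MVMR: exposure %s has all-zero betas; dropped", n)
    names = [n for n in names if n not in zero]
    if not names:
        raise FitError("every exposure has all-zero betas")
    k, m = len(merged), len(names)
    if k <= m:
        raise FitError("MVMR needs more variants than exposures")
    B = merged[names].to_numpy(float)
    if np.linalg.matrix_rank(B) < m:
        corr = np.corrcoef(B, rowvar=False)
        pairs = [(names[i], names[j]) for i in range(m) for j in range(i + 1, m)
                 if abs(corr[i, j]) > 0.999]
        raise FitError(f"rank-deficient exposure-beta matrix; collinear: {pairs}")
    by = merged["by"].to_numpy(float)
    w = 1.0 / merged["se_y"].to_numpy(float) ** 2
    res = sm.WLS(by, B, weights=w).fit()
    scale = _mre_scale(res.ssr, k - m)
    se = np.sqrt(np.diag(res.normalized_cov_params)) * scale
    z = res.params / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "exposure": names,
        "estimate": res.params,
        "se": se,
        "p": p,
        "k_variants": k,
        "dedup_rule": "variant identity (no LD pruning)",
    })
    return out.reset_index(drop=True)
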