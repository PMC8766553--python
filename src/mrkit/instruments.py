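"""Genetic risk scores: allele harmonisation, score construction, strength.

Dosages are aligned to published instrument weights by matching effect
alleles directly, after swapping, or after strand complement; palindromic
(A/T, C/G) variants are resolved by allele frequency when both studies are
far enough from 0.5, and dropped otherwise. In-sample weight estimation is
provided for instruments that lack external sex-stratified effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mrkit._glm import FitError, simple_slopes
from mrkit.synth import Cohort

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# palindromic variants are frequency-resolvable only when both eafs are
# outside [0.42, 0.58]
PALINDROME_EAF_MARGIN = 0.08

REQUIRED_COLUMNS = ("snp", "effect_allele", "other_allele", "weight")


@dataclass
class InstrumentSet:
    """Variants with effect/other alleles, weights and frequencies.

    ``table`` columns: snp, effect_allele, other_allele, weight, eaf
    (eaf may be NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"instrument table missing columns: {missing}")
        t = self.table.copy()
        for col in ("effect_allele", "other_allele"):
            t[col] = t[col].astype(str).str.upper()
        if "eaf" not in t.columns:
            t["eaf"] = np.nan
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect and other allele must differ")
        if not np.all(np.isfinite(t["weight"].astype(float))):
            raise ValueError("instrument weights must be finite")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele.upper())


def is_palindromic(a1: str, a2: str) -> bool:
    return complement(a1) == a2.upper()


def resolve_orientation(
    ea_ref: str, oa_ref: str, eaf_ref,
    ea_other: str, oa_other: str, eaf_other,
):
    """How the 'other' record maps onto the reference orientation.

    Returns +1 (same orientation), -1 (effect/other swapped) or None
    (unresolvable — allele mismatch, or palindromic with uninformative
    frequencies).
    """
    ea_ref, oa_ref = ea_ref.upper(), oa_ref.upper()
    ea_other, oa_other = ea_other.upper(), oa_other.upper()

    if is_palindromic(ea_ref, oa_ref):
        if {ea_other, oa_other} != {ea_ref, oa_ref}:
            return None
        if eaf_ref is None or eaf_other is None:
            return None
        eaf_ref, eaf_other = float(eaf_ref), float(eaf_other)
        if not (np.isfinite(eaf_ref) and np.isfinite(eaf_other)):
            return None
        if (abs(eaf_ref - 0.5) <= PALINDROME_EAF_MARGIN
                or abs(eaf_other - 0.5) <= PALINDROME_EAF_MARGIN):
            return None
        return 1 if (eaf_ref > 0.5) == (eaf_other > 0.5) else -1

    if (ea_other, oa_other) == (ea_ref, oa_ref):
        return 1
    if (ea_other, oa_other) == (oa_ref, ea_ref):
        return -1
    cea, coa = complement(ea_other), complement(oa_other)
    if (cea, coa) == (ea_ref, oa_ref):
        return 1
    if (cea, coa) == (oa_ref, ea_ref):
        return -1
    return None


def align_dosages(cohort: Cohort, iset: InstrumentSet):
    """Orient cohort dosages to the instrument set's effect alleles.

    Returns ``(aligned, kept)``: an n x k matrix counting each instrument's
    effect allele, plus the retained InstrumentSet in matrix column order.
    Unresolvable variants are dropped with a warning; losing more than half
    the instruments is a hard error.
    """
    meta = cohort.variant_meta.set_index("snp")
    cols, kept_rows, dropped = [], [], []
    for _, inst in iset.table.iterrows():
        snp = inst["snp"]
        if snp not in meta.index:
            dropped.append((snp, "absent from cohort"))
            continue
        var = meta.loc[snp]
        orient = resolve_orientation(
            inst["effect_allele"], inst["other_allele"], inst.get("eaf"),
            str(var["effect_allele"]), str(var["other_allele"]), var.get("eaf"),
        )
        if orient is None:
            dropped.append((snp, "unresolvable orientation"))
            continue
        j = meta.index.get_loc(snp)
        d = cohort.dosages[:, j]
        cols.append(d if orient == 1 else 2.0 - d)
        kept_rows.append(inst)
    for snp, why in dropped:
        log.warning("instrument %s dropped: %s", snp, why)
    if len(kept_rows) * 2 < len(iset):
        raise FitError(
            f"harmonisation dropped {len(dropped)}/{len(iset)} instruments")
    aligned = np.column_stack(cols) if cols else np.empty((cohort.n, 0))
    return aligned, InstrumentSet(pd.DataFrame(kept_rows).reset_index(drop=True))


def compute_grs(aligned: np.ndarray, iset: InstrumentSet) -> np.ndarray:
    """Additive genetic risk score: weighted sum of aligned dosages.

    Missing dosages contribute weight * 2 * eaf when the instrument's eaf is
    known, otherwise weight times the variant's sample-mean dosage.
    """
    aligned = np.asarray(aligned, dtype=float)
    weights = iset.table["weight"].to_numpy(dtype=float)
    if aligned.shape[1] != weights.size:
        raise ValueError("aligned matrix and weights disagree in length")
    filled = aligned
    if np.isnan(aligned).any():
        filled = aligned.copy()
        eaf = iset.table["eaf"].to_numpy(dtype=float)
        for j in range(filled.shape[1]):
            miss = np.isnan(filled[:, j])
            if not miss.any():
                continue
            fill = 2.0 * eaf[j] if np.isfinite(eaf[j]) else np.nanmean(aligned[:, j])
            filled[miss, j] = fill
    return filled @ weights


@dataclass
class StrengthResult:
    """Instrument-strength diagnostics from regressing exposure on the GRS."""

    r_squared: float
    f_statistic: float
    n: int


def instrument_strength(grs: np.ndarray, exposure: np.ndarray) -> StrengthResult:
    """R^2 and F = (n-2) R^2 / (1-R^2) from exposure ~ GRS."""
    grs = np.asarray(grs, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    ok = np.isfinite(grs) & np.isfinite(exposure)
    grs, exposure = grs[ok], exposure[ok]
    n = grs.size
    if n < 3:
        raise FitError("need at least 3 complete pairs")
    if np.var(grs) == 0.0:
        raise FitError("zero-variance GRS")
    r = np.corrcoef(grs, exposure)[0, 1]
    r2 = float(r * r)
    if r2 >= 1.0:
        raise FitError("perfect fit: F statistic undefined")
    f = (n - 2) * r2 / (1.0 - r2)
    return StrengthResult(r_squared=r2, f_statistic=float(f), n=int(n))


def estimate_weights_in_sample(
    cohort: Cohort,
    variant_ids,
    exclude_mask,
    sex: str,
    exposure_col: str = "exposure",
) -> InstrumentSet:
    """Per-variant weights from in-sample regression, in cancer-free participants.

    Each weight is the slope of a simple linear regression of the exposure on
    the variant's dosage, computed within participants of the given sex after
    applying ``exclude_mask`` (True = drop, e.g. any cancer diagnosis).
    Monomorphic variants are dropped with a warning.
    """
    ph = cohort.phenotypes
    exclude_mask = np.asarray(exclude_mask, dtype=bool)
    keep = (ph["sex"].to_numpy() == sex) & ~exclude_mask
    if not keep.any():
        raise FitError("exclusion mask removes every participant")

    meta = cohort.variant_meta.set_index("snp")
    idx = [meta.index.get_loc(v) for v in variant_ids]
    D = cohort.dosages[np.ix_(np.flatnonzero(keep), idx)]
    y = ph.loc[keep, exposure_col].to_numpy(dtype=float)

    beta, se, _ = simple_slopes(y, D)
    rows = []
    for k, vid in enumerate(variant_ids):
        if not np.isfinite(beta[k]):
            log.warning("variant %s monomorphic in estimation sample; dropped", vid)
            continue
        var = meta.loc[vid]
        rows.append({
            "snp": vid,
            "effect_allele": var["effect_allele"],
            "other_allele": var["other_allele"],
            "weight": float(beta[k]),
            "eaf": float(np.nanmean(D[:, k]) / 2.0),
            "se": float(se[k]),
        })
    if not rows:
        raise FitError("no estimable variants")
    return InstrumentSet(pd.DataFrame(rows))
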