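"""Phenotype derivation and filtering rules.

Case/control/excluded labelling from diagnosis codes (invasive vs in-situ),
incident-only filtering against a baseline date, menopause and workplace
chemical-exposure strata, waist-to-hip ratio, z-standardisation, and the
MAF/INFO variant filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
EXCLUDED = "excluded"

FREQUENT = "frequent"
INFREQUENT = "infrequent"
UNKNOWN = "unknown"

_FREQUENT_ANSWERS = {"Often", "Sometimes"}


def derive_cases(
    records: pd.DataFrame,
    participants: pd.DataFrame,
    sex: str,
    invasive_code: str,
    insitu_code: str,
) -> pd.Series:
    """Label each same-sex participant case / control / excluded.

    ``records`` is a long table with columns participant_id, code (and
    optionally date); ``participants`` maps participant_id to sex. A
    participant with any diagnosis code prefixed by ``invasive_code`` is a
    case; one with only ``insitu_code``-prefixed entries is excluded;
    anyone else is a control. Records belonging to participants of the
    other sex are ignored with a warning. Matching is by code prefix, so
    C50 matches C50, C501, C509.
    """
    participants = participants.set_index("participant_id") if "participant_id" in participants.columns else participants
    same_sex = participants.index[participants["sex"] == sex]

    rec = records.copy()
    rec["code"] = rec["code"].astype(str)
    if (rec["code"] == "").any():
        raise ValueError("diagnosis records must carry a non-empty code")
    known = rec["participant_id"].isin(participants.index)
    wrong_sex = known & ~rec["participant_id"].isin(same_sex)
    if wrong_sex.any():
        log.warning("ignoring %d diagnosis records for wrong-sex participants",
                    int(wrong_sex.sum()))
    rec = rec.loc[known & ~wrong_sex]

    invasive = set(rec.loc[rec["code"].str.startswith(invasive_code), "participant_id"])
    insitu = set(rec.loc[rec["code"].str.startswith(insitu_code), "participant_id"])

    status = pd.Series(CONTROL, index=same_sex, name="status", dtype=object)
    status.loc[status.index.isin(insitu - invasive)] = EXCLUDED
    status.loc[status.index.isin(invasive)] = CASE
    return status


def filter_incident(
    sample: pd.DataFrame,
    baseline_date,
    status_col: str = "status",
    date_col: str = "diagnosis_date",
) -> pd.DataFrame:
    """Drop prevalent cases (earliest diagnosis before baseline).

    Controls pass through untouched. Cases with a missing diagnosis date
    cannot be classified and are removed with a warning. Idempotent.
    """
    baseline_date = pd.Timestamp(baseline_date)
    is_case = sample[status_col] == CASE
    dates = pd.to_datetime(sample[date_col], errors="coerce")
    undated = is_case & dates.isna()
    if undated.any():
        log.warning("excluding %d cases with missing diagnosis dates",
                    int(undated.sum()))
    prevalent = is_case & (dates < baseline_date)
    return sample.loc[~(prevalent | undated)].copy()


def derive_menopause_stratum(
    sample: pd.DataFrame,
    status_col: str = "status",
    diag_age_col: str = "age_at_diagnosis",
    meno_age_col: str = "age_at_menopause",
    baseline_status_col: str = "menopause_baseline",
) -> pd.Series:
    """Pre/post-menopausal stratum labels.

    Cases: pre if diagnosed before the reported menopause age, or if
    menopause had not occurred by diagnosis (no menopause age reported but
    the baseline status is pre); otherwise post. Controls: their baseline
    status. Indeterminate participants are set to unknown.
    """
    is_case = sample[status_col] == CASE
    diag_age = pd.to_numeric(sample[diag_age_col], errors="coerce")
    meno_age = pd.to_numeric(sample[meno_age_col], errors="coerce")
    baseline = sample[baseline_status_col].astype(str).replace("", UNKNOWN)
    baseline = baseline.where(baseline.isin(["pre", "post"]), UNKNOWN)

    out = pd.Series(UNKNOWN, index=sample.index, dtype=object, name="menopause")
    out.loc[~is_case] = baseline.loc[~is_case]

    both = is_case & diag_age.notna() & meno_age.notna()
    out.loc[both & (diag_age < meno_age)] = "pre"
    out.loc[both & (diag_age >= meno_age)] = "post"
    # menopause age unreported: fall back to baseline status when it says pre
    not_yet = is_case & diag_age.notna() & meno_age.isna() & (baseline == "pre")
    out.loc[not_yet] = "pre"
    return out


def derive_chemical_exposure(answers: pd.DataFrame) -> pd.Series:
    """Workplace chemical-exposure stratum from the seven occupation fields.

    frequent iff any field was ever answered Often or Sometimes; unknown if
    every field is missing; infrequent otherwise.
    """
    vals = answers.astype(object)
    isfreq = vals.isin(_FREQUENT_ANSWERS)
    missing = vals.isna() | (vals == "")
    out = pd.Series(INFREQUENT, index=answers.index, dtype=object, name="chemical")
    out.loc[isfreq.any(axis=1)] = FREQUENT
    out.loc[missing.all(axis=1)] = UNKNOWN
    return out


def compute_whr(wc, hc):
    """Waist-to-hip ratio wc/hc; missing when hc is missing or <= 0."""
    wc = np.asarray(wc, dtype=float)
    hc = np.asarray(hc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.isfinite(hc) & (hc > 0), wc / hc, np.nan)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def standardise(values: pd.Series) -> pd.Series:
    """Z-scores over non-missing entries (mean 0, variance 1); NaN preserved."""
    v = pd.to_numeric(pd.Series(values), errors="coerce")
    nonmiss = v.dropna()
    if len(nonmiss) < 2:
        raise ValueError("need at least 2 non-missing values to standardise")
    sd = nonmiss.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance: cannot standardise")
    return (v - nonmiss.mean()) / sd


def filter_variants(variants: pd.DataFrame,
                    maf_col: str = "maf",
                    info_col: str = "info") -> pd.DataFrame:
    """Keep variants with MAF >= 0.01 and INFO >= 0.8 (missing INFO = genotyped, kept)."""
    maf = pd.to_numeric(variants[maf_col], errors="coerce")
    keep = maf >= 0.01
    if info_col in variants.columns:
        info = pd.to_numeric(variants[info_col], errors="coerce")
        keep &= info.isna() | (info >= 0.8)
    return variants.loc[keep].copy()
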