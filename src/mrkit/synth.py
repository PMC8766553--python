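"""Synthetic cohorts and two-sample summary studies with known causal structure.

Generates biallelic SNP dosages under Hardy–Weinberg equilibrium, a
continuous exposure driven by the SNPs plus an unobserved confounder, a
binary outcome from a logistic model with a configurable causal effect,
optional per-SNP pleiotropy and stratum-specific effect modification,
diagnosis codes/dates (incident vs prevalent), menopause and workplace
exposure fields, and two-sample summary statistics from non-overlapping
samples. Every downstream estimator can therefore be checked against a
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from mrkit._glm import logistic_slopes, simple_slopes

log = logging.getLogger(__name__)

BASELINE_DATE = pd.Timestamp("2010-01-01")

# substream keys: one per stochastic stage so stages stay independently
# reproducible under a single global seed
_S_GENO = 1
_S_CONF = 2
_S_NOISE = 3
_S_OUTCOME = 4
_S_DATES = 5
_S_STRATA = 6
_S_AGE = 7
_S_MENO = 8
_S_CHEM = 9
_S_EXPO_SAMPLE = 10
_S_OUTC_SAMPLE = 11

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]

WORKPLACE_FIELDS = [
    "workplace_dusty",
    "workplace_fumes",
    "workplace_smoke",
    "workplace_asbestos",
    "workplace_paints",
    "workplace_pesticides",
    "workplace_diesel",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    The exposure is X = G @ snp_effects + confounder_effect_x * U + eps with
    U ~ N(0,1) and eps ~ N(0, noise_sd^2). The binary outcome is Bernoulli
    with logit = baseline_logit + theta_stratum * X + confounder_effect_y * U
    + G @ pleiotropy, where theta_stratum = theta times the stratum's
    multiplier from ``stratum_spec`` (1 if unset).
    """

    n_individuals: int
    mafs: Sequence[float]
    snp_effects: Sequence[float]
    theta: float = 0.0
    confounder_effect_x: float = 0.0
    confounder_effect_y: float = 0.0
    pleiotropy: Sequence[float] | None = None
    baseline_logit: float = -4.0
    stratum_spec: Mapping[str, float] | None = None
    prevalent_fraction: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    sex: str = "female"
    invasive_code: str = "C50"
    insitu_code: str = "D05"

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        mafs = np.asarray(self.mafs, dtype=float)
        if mafs.ndim != 1 or mafs.size == 0:
            raise ValueError("mafs must be a non-empty 1-d sequence")
        if np.any(mafs <= 0.0) or np.any(mafs >= 1.0):
            raise ValueError("maf out of range: all mafs must lie in (0, 1)")
        effects = np.asarray(self.snp_effects, dtype=float)
        if effects.shape != mafs.shape:
            raise ValueError("snp_effects length must match mafs")
        if self.pleiotropy is None:
            self.pleiotropy = np.zeros_like(effects)
        pleio = np.asarray(self.pleiotropy, dtype=float)
        if pleio.shape != mafs.shape:
            raise ValueError("pleiotropy length must match mafs")
        if not 0.0 <= self.prevalent_fraction <= 1.0:
            raise ValueError("prevalent_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.mafs = mafs
        self.snp_effects = effects
        self.pleiotropy = pleio

    @property
    def n_variants(self) -> int:
        return len(self.mafs)


@dataclass
class Cohort:
    """Individual-level analysis unit: phenotypes + aligned dosages.

    ``phenotypes`` has one row per participant; ``dosages`` is a
    participants x variants matrix of effect-allele counts in [0, 2];
    ``variant_meta`` carries per-variant id, effect allele, other allele and
    effect-allele frequency. The ``confounder_oracle`` phenotype column is
    for oracle checks in tests only — analysis code must never read it.
    """

    phenotypes: pd.DataFrame
    dosages: np.ndarray
    variant_meta: pd.DataFrame
    baseline_date: pd.Timestamp = BASELINE_DATE

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape[0] != len(self.phenotypes):
            raise ValueError("dosage rows must match phenotype rows")
        if self.dosages.shape[1] != len(self.variant_meta):
            raise ValueError("dosage columns must match variant_meta rows")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.phenotypes)


@dataclass
class TwoSampleStudy:
    """Summary statistics from two non-overlapping simulated samples."""

    exposure_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    truth: SimulationConfig

    def __post_init__(self) -> None:
        shared = set(self.exposure_stats["snp"]) & set(self.outcome_stats["snp"])
        if not shared:
            raise ValueError("exposure and outcome studies share no variants")


def simulate_genotypes(n: int, mafs: Sequence[float], seed: int) -> np.ndarray:
    """Draw an n x m dosage matrix with column j ~ Binomial(2, maf_j)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0.0) or np.any(mafs >= 1.0):
        raise ValueError("maf out of range: all mafs must lie in (0, 1)")
    rng = _rng(seed, _S_GENO)
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(float)


def variant_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic per-variant ids, alleles and frequencies."""
    rows = []
    for j, maf in enumerate(config.mafs):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        rows.append({"snp": f"rs{j + 1}", "effect_allele": ea,
                     "other_allele": oa, "eaf": float(maf)})
    return pd.DataFrame(rows)


def _draw_exposure_outcome(config: SimulationConfig, n: int, seed: int):
    """Core generative draw shared by cohorts and summary-stat samples."""
    G = simulate_genotypes(n, config.mafs, seed)
    U = _rng(seed, _S_CONF).standard_normal(n)
    eps = _rng(seed, _S_NOISE).standard_normal(n) * config.noise_sd
    X = G @ config.snp_effects + config.confounder_effect_x * U + eps

    if config.stratum_spec:
        labels = sorted(config.stratum_spec)
        assign = _rng(seed, _S_STRATA).integers(0, len(labels), size=n)
        stratum = np.array(labels, dtype=object)[assign]
        mult = np.array([config.stratum_spec[lab] for lab in labels])[assign]
    else:
        stratum = np.full(n, "all", dtype=object)
        mult = np.ones(n)

    eta = (config.baseline_logit + config.theta * mult * X
           + config.confounder_effect_y * U + G @ config.pleiotropy)
    Y = (_rng(seed, _S_OUTCOME).random(n) < expit(eta)).astype(int)
    return G, U, X, Y, stratum


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full individual-level cohort from ``config``."""
    n, seed = config.n_individuals, config.seed
    G, U, X, Y, stratum = _draw_exposure_outcome(config, n, seed)

    age = _rng(seed, _S_AGE).integers(40, 70, size=n).astype(float)

    # diagnosis codes and dates; a prevalent_fraction of cases predates baseline
    rng_d = _rng(seed, _S_DATES)
    code = np.full(n, "", dtype=object)
    date = np.full(n, pd.NaT, dtype=object)
    case_idx = np.flatnonzero(Y == 1)
    if case_idx.size:
        prevalent = rng_d.random(case_idx.size) < config.prevalent_fraction
        offsets = rng_d.integers(1, 3000, size=case_idx.size)
        for i, idx in enumerate(case_idx):
            code[idx] = config.invasive_code
            days = -int(offsets[i]) if prevalent[i] else int(offsets[i])
            date[idx] = BASELINE_DATE + pd.Timedelta(days=days)

    rng_m = _rng(seed, _S_MENO)
    meno_age = rng_m.normal(50.0, 3.0, size=n)
    meno_missing = rng_m.random(n) < 0.1
    meno_age[meno_missing] = np.nan
    baseline_status = np.where(
        np.isnan(meno_age), "", np.where(meno_age <= age, "post", "pre")
    ).astype(object)

    rng_c = _rng(seed, _S_CHEM)
    chem = {
        f: rng_c.choice(["Often", "Sometimes", "Rarely/never", ""],
                        size=n, p=[0.05, 0.10, 0.75, 0.10])
        for f in WORKPLACE_FIELDS
    }

    diag_age = np.full(n, np.nan)
    for idx in case_idx:
        delta_years = (date[idx] - BASELINE_DATE).days / 365.25
        diag_age[idx] = age[idx] + delta_years

    pheno = pd.DataFrame({
        "participant_id": [f"ID{i:07d}" for i in range(n)],
        "sex": config.sex,
        "age": age,
        "exposure": X,
        "case": Y,
        "diagnosis_code": code,
        "diagnosis_date": pd.to_datetime(pd.Series(date)),
        "age_at_diagnosis": diag_age,
        "stratum": stratum,
        "age_at_menopause": meno_age,
        "menopause_baseline": baseline_status,
        "confounder_oracle": U,
        **chem,
    })
    return Cohort(phenotypes=pheno, dosages=G, variant_meta=variant_metadata(config))


def diagnosis_records(cohort: Cohort) -> pd.DataFrame:
    """Long-format (participant_id, code, date) table of diagnosis events."""
    ph = cohort.phenotypes
    mask = ph["diagnosis_code"].astype(str) != ""
    return (ph.loc[mask, ["participant_id", "diagnosis_code", "diagnosis_date"]]
              .rename(columns={"diagnosis_code": "code", "diagnosis_date": "date"})
              .reset_index(drop=True))


def simulate_summary_stats(
    config: SimulationConfig,
    n_exposure: int,
    n_outcome: int,
    seed: int,
) -> TwoSampleStudy:
    """Two-sample summary statistics from independent simulated samples.

    Sample A yields per-SNP linear-regression estimates of the SNP–exposure
    association; sample B yields per-SNP logistic-regression estimates of
    the SNP–outcome association. Monomorphic simulated variants are dropped
    with a warning.
    """
    meta = variant_metadata(config)

    Ga, _, Xa, _, _ = _draw_exposure_outcome(config, n_exposure, _mix(seed, _S_EXPO_SAMPLE))
    Gb, _, _, Yb, _ = _draw_exposure_outcome(config, n_outcome, _mix(seed, _S_OUTC_SAMPLE))

    bx, se_x, p_x = simple_slopes(Xa, Ga)
    by, se_y, p_y = logistic_slopes(Yb, Gb)

    def _table(G, beta, se, p, n):
        df = meta.copy()
        df["eaf"] = G.mean(axis=0) / 2.0
        df["beta"] = beta
        df["se"] = se
        df["pval"] = p
        df["n"] = n
        keep = np.isfinite(df["beta"]) & np.isfinite(df["se"])
        dropped = int((~keep).sum())
        if dropped:
            log.warning("dropped %d monomorphic/unfittable variants", dropped)
        return df.loc[keep].reset_index(drop=True)

    return TwoSampleStudy(
        exposure_stats=_table(Ga, bx, se_x, p_x, n_exposure),
        outcome_stats=_table(Gb, by, se_y, p_y, n_outcome),
        truth=config,
    )


def _mix(seed: int, stream: int) -> int:
    """Derive a child seed so samples A/B share no generator stream."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63))
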