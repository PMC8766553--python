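"""End-to-end pipeline: phenotype prep -> GRS -> one/two-sample, non-linear
MR and the confounder search, with per-stage result tables and a run log."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mrkit import io as mio
from mrkit import phenotypes as ph
from mrkit._glm import FitError
from mrkit.confounders import screen_candidates, stepwise_attenuation
from mrkit.instruments import (InstrumentSet, align_dosages, compute_grs,
                               instrument_strength)
from mrkit.nonlinear import WindowSpec, plot_profile, sliding_profile
from mrkit.onesample import (bootstrap_ci, exclusion_restriction_test,
                             heterogeneity_test, observational_association,
                             stratified_mr, two_stage_mr)
from mrkit.synth import Cohort, SimulationConfig, diagnosis_records, simulate_cohort, simulate_summary_stats
from mrkit.twosample import egger, harmonise, ivw

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    phenotypes: str
    dosages: str
    instruments: str
    diagnoses: str
    exposure_stats: str | None = None
    outcome_stats: str | None = None
    exposure_col: str = "exposure"
    sex: str = "female"
    invasive_code: str = "C50"
    insitu_code: str = "D05"
    baseline_date: str = "2010-01-01"
    strata_columns: list = field(default_factory=lambda: ["chemical"])
    bootstrap_reps: int = 0
    window_size: int = 50000
    step_size: int = 1000
    per_window_denominator: bool = False
    run_nonlinear: bool = True
    confounder_candidates: list = field(default_factory=list)
    confounder_tolerance: float = 0.01
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for attr in ("phenotypes", "dosages", "instruments", "diagnoses"):
            p = getattr(self, attr)
            if not p:
                raise ValueError(f"config requires a {attr} path")
            if not Path(p).exists():
                raise ValueError(f"{attr} path does not exist: {p}")
        for attr in ("exposure_stats", "outcome_stats"):
            p = getattr(self, attr)
            if p and not Path(p).exists():
                raise ValueError(f"{attr} path does not exist: {p}")


def simulate_to_dir(config: SimulationConfig, outdir,
                    n_summary: int | None = None) -> dict:
    """Generate a cohort plus two-sample stats and write every artefact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    mio.write_phenotypes(cohort.phenotypes, outdir / "phenotypes.tsv")
    mio.write_dosages_tsv(cohort.phenotypes["participant_id"], cohort.dosages,
                          cohort.variant_meta["snp"], outdir / "dosages.tsv")
    mio._write_tsv(cohort.variant_meta, outdir / "variants.tsv")
    recs = diagnosis_records(cohort)
    recs["date"] = recs["date"].dt.strftime("%Y-%m-%d")
    mio._write_tsv(recs, outdir / "diagnoses.tsv")

    inst = cohort.variant_meta.copy()
    inst["beta"] = np.asarray(config.snp_effects, dtype=float)
    mio._write_tsv(inst, outdir / "instruments.tsv")

    n_sum = n_summary or config.n_individuals
    study = simulate_summary_stats(config, n_sum, n_sum, config.seed)
    mio.write_summary_stats(study.exposure_stats, outdir / "exposure_stats.tsv")
    mio.write_summary_stats(study.outcome_stats, outdir / "outcome_stats.tsv")

    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(config).items()}
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return {"n": cohort.n, "n_variants": len(cohort.variant_meta)}


def _load_cohort(cfg: RunConfig) -> Cohort:
    pheno = mio.read_phenotypes(cfg.phenotypes)
    if str(cfg.dosages).endswith(".vcf"):
        ids, mat, meta = mio.read_vcf_dosages(cfg.dosages)
    else:
        ids, mat, vids = mio.read_dosages_tsv(cfg.dosages)
        meta = pd.DataFrame({"snp": vids})
    inst_meta = mio.read_instruments(cfg.instruments)
    # variant alleles/frequencies travel with the instrument file when the
    # dosage TSV carries none
    if "effect_allele" not in meta.columns:
        meta = meta.merge(
            inst_meta[["snp", "effect_allele", "other_allele", "eaf"]],
            on="snp", how="left")
    id_to_row = {pid: i for i, pid in enumerate(ids)}
    keep = pheno["participant_id"].isin(id_to_row)
    if (~keep).any():
        log.warning("%d participants lack genotypes; dropped", int((~keep).sum()))
        pheno = pheno.loc[keep].reset_index(drop=True)
    rows = [id_to_row[p] for p in pheno["participant_id"]]
    return Cohort(phenotypes=pheno, dosages=mat[rows], variant_meta=meta,
                  baseline_date=pd.Timestamp(cfg.baseline_date))


def _fit_row(name: str, fit, stratum: str = "all", extra: dict | None = None):
    row = {
        "method": name, "stratum": stratum,
        "log_or": fit.log_or_per_sd, "or": fit.odds_ratio,
        "ci_low": fit.ci_low, "ci_high": fit.ci_high,
        "p": mio.format_p(fit.p),
        "n_cases": fit.n_cases, "n_controls": fit.n_controls,
    }
    row.update(extra or {})
    return row


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute every configured stage; write tables, log, and return a summary.

    A failing stage aborts with its name in the error; tables written by
    earlier stages are preserved.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": {}, "dropped": {}}
    stage = "load"
    try:
        cohort = _load_cohort(cfg)
        records = mio._read_tsv(cfg.diagnoses)

        # ---- phenotype prep -------------------------------------------------
        stage = "phenotype_prep"
        status = ph.derive_cases(
            records, cohort.phenotypes[["participant_id", "sex"]],
            cfg.sex, cfg.invasive_code, cfg.insitu_code)
        sample = cohort.phenotypes.set_index("participant_id").loc[status.index]
        sample["status"] = status
        n_total = len(sample)
        sample = sample.loc[sample["status"] != ph.EXCLUDED]
        sample = ph.filter_incident(sample, cfg.baseline_date)
        summary["dropped"]["excluded_or_prevalent"] = n_total - len(sample)
        sample["exposure_z"] = ph.standardise(sample[cfg.exposure_col])
        sample["chemical"] = ph.derive_chemical_exposure(
            sample[[c for c in sample.columns if c.startswith("workplace_")]])
        if cfg.sex == "female" and "age_at_menopause" in sample.columns:
            sample["menopause"] = ph.derive_menopause_stratum(sample)
        case = (sample["status"] == ph.CASE).astype(float).to_numpy()
        age = pd.to_numeric(sample["age"]).to_numpy(float)
        expo = sample["exposure_z"].to_numpy(float)
        summary["stages"]["phenotype_prep"] = {
            "n": len(sample), "n_cases": int(case.sum())}

        # ---- instruments ----------------------------------------------------
        stage = "instruments"
        iset = InstrumentSet(mio.read_instruments(cfg.instruments))
        sub = Cohort(phenotypes=sample.reset_index(),
                     dosages=cohort.dosages[
                         cohort.phenotypes["participant_id"].isin(sample.index).to_numpy()],
                     variant_meta=cohort.variant_meta)
        aligned, kept = align_dosages(sub, iset)
        grs = compute_grs(aligned, kept)
        strength = instrument_strength(grs, expo)
        mio._write_tsv(pd.DataFrame([{
            "n_instruments": len(kept), "r_squared": strength.r_squared,
            "f_statistic": strength.f_statistic, "n": strength.n,
        }]), outdir / "grs_strength.tsv")
        summary["stages"]["instruments"] = {"kept": len(kept),
                                            "dropped": len(iset) - len(kept)}

        # ---- one-sample MR --------------------------------------------------
        stage = "one_sample_mr"
        rows = []
        obs = observational_association(expo, case, age)
        rows.append(_fit_row("observational", obs))
        ts = two_stage_mr(expo, grs, case, age)
        if cfg.bootstrap_reps:
            lo, hi = bootstrap_ci(expo, grs, case, age,
                                  reps=cfg.bootstrap_reps, seed=cfg.seed)
            ts.ci_low, ts.ci_high = lo, hi
            ts.diagnostics["bootstrap_reps"] = cfg.bootstrap_reps
        rows.append(_fit_row("two-stage", ts,
                             extra={"stage1_f": ts.diagnostics["stage1_f"]}))
        er_coef, er_se, er_p = exclusion_restriction_test(case, grs, expo, age)
        mio._write_tsv(pd.DataFrame(rows), outdir / "onesample.tsv")
        mio._write_tsv(pd.DataFrame([{
            "grs_coefficient": er_coef, "se": er_se, "p": mio.format_p(er_p),
        }]), outdir / "exclusion_restriction.tsv")
        summary["stages"]["one_sample_mr"] = {"log_or": ts.log_or_per_sd}

        # ---- stratified -----------------------------------------------------
        stage = "stratified_mr"
        strat_rows = []
        for col in cfg.strata_columns:
            if col not in sample.columns:
                log.warning("stratum column %s absent; skipped", col)
                continue
            try:
                fits = stratified_mr(expo, grs, case, age,
                                     sample[col].to_numpy(object))
            except FitError as exc:
                log.warning("stratified MR on %s skipped: %s", col, exc)
                continue
            het = heterogeneity_test(
                [f.log_or_per_sd for f in fits.values()],
                [f.se for f in fits.values()])
            for lab, f in sorted(fits.items()):
                strat_rows.append(_fit_row("two-stage", f, stratum=f"{col}={lab}",
                                           extra={"het_q": het.Q,
                                                  "het_p": mio.format_p(het.p),
                                                  "i_squared": het.i_squared}))
        mio._write_tsv(pd.DataFrame(strat_rows), outdir / "stratified.tsv")

        # ---- two-sample MR --------------------------------------------------
        stage = "two_sample_mr"
        if cfg.exposure_stats and cfg.outcome_stats:
            est = mio.read_summary_stats(cfg.exposure_stats)
            ost = mio.read_summary_stats(cfg.outcome_stats)
            study = harmonise(est, ost)
            rows2 = []
            fit = ivw(study)
            rows2.append(_fit_row("IVW (MRE)", fit,
                                  extra={"k": fit.diagnostics["k"],
                                         "intercept_p": ""}))
            if study.k >= 3:
                eg = egger(study)
                rows2.append({
                    "method": "MR Egger", "stratum": "all",
                    "log_or": eg.slope, "or": float(np.exp(eg.slope)),
                    "ci_low": eg.ci_low, "ci_high": eg.ci_high,
                    "p": mio.format_p(eg.slope_p), "n_cases": 0,
                    "n_controls": 0, "k": eg.k,
                    "intercept_p": mio.format_p(eg.intercept_p),
                })
            mio._write_tsv(pd.DataFrame(rows2), outdir / "twosample.tsv")
            summary["dropped"]["harmonisation"] = study.drop_reasons
            summary["stages"]["two_sample_mr"] = {"k": study.k}
            # MVMR needs >= 2 exposures; a single simulated exposure cannot
            # populate it, so it is logged as skipped rather than fabricated
            summary["stages"]["mvmr"] = "skipped: single exposure configured"

        # ---- non-linear MR --------------------------------------------------
        stage = "nonlinear_mr"
        if cfg.run_nonlinear and len(sample) >= cfg.window_size:
            spec = WindowSpec(cfg.window_size, cfg.step_size)
            profile = sliding_profile(
                expo, grs, case, age, spec,
                per_window_denominator=cfg.per_window_denominator)
            mio._write_tsv(profile.table, outdir / "nonlinear.tsv")
            if cfg.make_plots:
                plot_profile(profile, outdir / "nonlinear.png")
            summary["stages"]["nonlinear_mr"] = {
                "windows": len(profile.table),
                "denominator": profile.denominator}
        elif cfg.run_nonlinear:
            summary["stages"]["nonlinear_mr"] = (
                f"skipped: n={len(sample)} < window_size={cfg.window_size}")

        # ---- confounder search ---------------------------------------------
        stage = "confounder_search"
        if cfg.confounder_candidates:
            work = sample.copy()
            work["case_flag"] = case
            cands = [c for c in cfg.confounder_candidates if c in work.columns]
            for missing in set(cfg.confounder_candidates) - set(cands):
                log.warning("candidate column %s absent; skipped", missing)
            eligible, report = screen_candidates(
                work, "exposure_z", "case_flag", cands)
            mio._write_tsv(report, outdir / "confounder_screen.tsv")
            trace = stepwise_attenuation(
                work, "exposure_z", "case_flag", eligible,
                tolerance=cfg.confounder_tolerance)
            mio._write_tsv(trace.steps, outdir / "confounder_trace.tsv")
            summary["stages"]["confounder_search"] = {
                "eligible": len(eligible), "selected": trace.selected,
                "initial_log_or": trace.initial_log_or,
                "stop_reason": trace.stop_reason}
    except FitError as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
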