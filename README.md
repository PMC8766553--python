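# mrkit

Genetic risk scores and Mendelian randomisation (MR) in Python: one-sample
(two-stage), two-sample (IVW, MR-Egger), multivariable, stratified and
non-linear (sliding-window) estimators, the phenotype-derivation rules that
feed them, a stepwise confounder-attenuation search, and a synthetic-cohort
generator with known causal structure so every estimator can be validated
against ground truth.

## What is in the box

| module | purpose |
| --- | --- |
| `mrkit.synth` | cohorts and two-sample summary studies simulated under Hardy–Weinberg with configurable causal effect, confounding, pleiotropy, stratum modification, incident/prevalent diagnosis dates |
| `mrkit.phenotypes` | case/control/excluded labelling from diagnosis codes (invasive vs in-situ, prefix matched), incident filtering, menopause and workplace-chemical strata, WHR, z-standardisation, MAF/INFO variant filter |
| `mrkit.instruments` | allele harmonisation of dosages to instrument weights (swaps, strand complements, palindromic frequency rule), additive GRS, R²/F instrument strength, in-sample weight estimation |
| `mrkit.onesample` | observational association, two-stage MR with percentile bootstrap CIs, exclusion-restriction test, stratified MR, Cochran-Q heterogeneity |
| `mrkit.twosample` | summary-statistics harmonisation, Wald ratio, IVW with multiplicative random effects, MR-Egger with intercept pleiotropy test, multivariable MR |
| `mrkit.nonlinear` | IV-free residual ordering, sliding windows, localized causal estimates, profile plots |
| `mrkit.confounders` | candidate screening (>1000 non-missing, associated with both exposure and outcome) and greedy \|ln(OR)\|-minimising forward selection |
| `mrkit.io`, `mrkit.pipeline`, `mrkit.cli` | TSV/VCF readers and writers, run configuration, the end-to-end pipeline and its CLI |

## Command line

Simulate a cohort with known truth, then run the whole pipeline:

```bash
mrkit simulate --config sim.yaml --out data/
mrkit run-all --config run.yaml --seed 11 --out results/
```

`sim.yaml` holds the generative parameters (`n_individuals`, `mafs`,
`snp_effects`, `theta`, confounder effects, `baseline_logit`,
`prevalent_fraction`, `seed`, optional `n_summary`). `run.yaml` points at the
phenotype/dosage/instrument/diagnosis files plus, optionally, two-sample
summary statistics, and sets strata, bootstrap repetitions, the sliding
window and confounder candidates — see `tests/test_io_cli.py` for a complete
example. Other subcommands run single stages: `prep`, `grs`, `mr-onesample`,
`mr-twosample`, `mr-mv`, `mr-nonlinear`, `confounder-search`.

Results are TSV tables (one per stage) plus `run_log.json`; reruns with the
same seed are byte-identical.

## Library example

```python
import mrkit

cfg = mrkit.SimulationConfig(
    n_individuals=100_000, mafs=[0.3] * 30, snp_effects=[0.12] * 30,
    theta=-0.3, confounder_effect_x=0.4, confounder_effect_y=0.4,
    baseline_logit=-3.5, seed=1)
cohort = mrkit.simulate_cohort(cfg)

iset = mrkit.InstrumentSet(cohort.variant_meta.assign(weight=0.12))
aligned, kept = mrkit.align_dosages(cohort, iset)
grs = mrkit.compute_grs(aligned, kept)

ph = cohort.phenotypes
fit = mrkit.two_stage_mr(ph["exposure"], grs, ph["case"], ph["age"])
print(fit.odds_ratio, fit.ci_low, fit.ci_high, fit.p)
```
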