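import numpy as np
import pytest

from mrkit.synth import SimulationConfig, simulate_cohort


def make_config(**overrides) -> SimulationConfig:
    """Small default design used across unit tests."""
    base = dict(
        n_individuals=20000,
        mafs=[0.3] * 10,
        snp_effects=[0.12] * 10,
        theta=0.0,
        confounder_effect_x=0.0,
        confounder_effect_y=0.0,
        baseline_logit=-3.0,
        noise_sd=1.0,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def true_instruments(config: SimulationConfig):
    """InstrumentSet carrying the generative per-SNP weights."""
    from mrkit.instruments import InstrumentSet
    from mrkit.synth import variant_metadata

    meta = variant_metadata(config)
    meta["weight"] = np.asarray(config.snp_effects, dtype=float)
    return InstrumentSet(meta)


def cohort_grs(cohort, config):
    from mrkit.instruments import align_dosages, compute_grs

    aligned, kept = align_dosages(cohort, true_instruments(config))
    return compute_grs(aligned, kept)


@pytest.fixture(scope="session")
def null_cohort():
    """theta = 0, no confounding, ~5% prevalence. Returns (config, cohort)."""
    cfg = make_config()
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def causal_cohort():
    """theta = -0.3 with confounding, rare outcome. Returns (config, cohort)."""
    cfg = make_config(
        n_individuals=60000, theta=-0.3,
        confounder_effect_x=0.4, confounder_effect_y=0.4,
        baseline_logit=-4.0, seed=5)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def confounded_null_cohort():
    """theta = 0 but strong positive confounding. Returns (config, cohort)."""
    cfg = make_config(
        n_individuals=60000, theta=0.0,
        confounder_effect_x=0.6, confounder_effect_y=0.6,
        baseline_logit=-3.5, seed=3)
    return cfg, simulate_cohort(cfg)
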