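import pytest

from pahrare.synth import SimulationConfig, generate_cohort


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A scaled-down study for fast unit tests (structure, not calibration)."""
    defaults = dict(
        seed=seed,
        n_discovery_cases=12,
        n_replication_cases=28,
        n_controls=60,
        case_carrier_freq=0.3,
        control_carrier_freq=0.02,
        n_background_genes=150,
        background_hit_rate=2.0,
        n_common_snps=2000,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study's default conditions (42/188 cases, 968 controls)."""
    return generate_cohort(SimulationConfig(seed=1))
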