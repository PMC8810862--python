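import numpy as np
import pytest

from mirpanel.config import SimulationConfig, SourceSpec, default_effects
from mirpanel.synth import simulate_study


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A three-phase study small enough for fast unit tests."""
    defaults = dict(
        n_mirnas=40,
        n_differential=12,
        n_reference=3,
        log2fc_effects=default_effects(12, 0.6, 1.4),
        sources=(
            SourceSpec("s1", "discovery", 40, 40),
            SourceSpec("s2", "validation1", 30, 30),
            SourceSpec("s3", "validation1", 25, 25),
            SourceSpec("s2", "validation2", 30, 30),
            SourceSpec("s3", "validation2", 25, 25),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def noise_free_config(seed: int = 3, **overrides) -> SimulationConfig:
    defaults = dict(
        n_mirnas=20,
        n_differential=5,
        n_reference=2,
        log2fc_effects=default_effects(5, 0.8, 1.2),
        sources=(SourceSpec("s1", "discovery", 10, 10),),
        ct_sd=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    cfg = small_config()
    table, truth, ct = simulate_study(cfg)
    return cfg, table, truth, ct


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
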