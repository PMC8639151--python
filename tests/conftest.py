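import numpy as np
import pytest
from hypothesis import settings

from quadgait import simulate as sim

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def conditions():
    return sim.default_conditions()


@pytest.fixture(scope="session")
def clean_params():
    """A degenerate, noise-free condition: perfect alternating gait."""
    return sim.ConditionParams(
        label="clean",
        phase_sd=1e-9,
        sync_mixture_weight=0.0,
        dorsal_prob=0.0,
        swing_sd=1e-9,
        stance_noise_cv=0.0,
        speed_jitter_cv=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort(conditions):
    """A small four-condition cohort shared by read-only tests."""
    cfg = sim.SyntheticConfig(
        conditions=list(conditions.values()),
        n_animals=2,
        passes_per_animal=2,
        strides_per_pass=(5, 7),
        seed=7,
        include_markers=False,
    )
    return sim.generate_cohort(cfg)
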