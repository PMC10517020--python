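import numpy as np
import pytest

from omicsurv.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_patients=160,
        features_per_modality={"mrna": 300, "mirna": 100, "lncrna": 150, "methylation": 400},
        missing_rate=0.02,
        missing_elevated_frac=0.05,
        subtype_shift=1.0,
        effect_size=0.8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_ph_survival(rng, lp, scale=1000.0, shape=1.2, censor_scale=None):
    """Weibull proportional-hazards sampler for test oracles (independent of
    the package generator)."""
    n = len(lp)
    u = rng.exponential(1.0, size=n)
    t = scale * (u / np.exp(lp)) ** (1.0 / shape)
    if censor_scale is None:
        return t, np.ones(n, dtype=bool)
    c = rng.exponential(censor_scale, size=n)
    return np.minimum(t, c), t <= c
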