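import numpy as np
import pytest

from coscore import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """A 200-sample, 40-feature cohort with no outcome-associated features."""
    cfg = SimulationConfig(
        n_samples=200, n_features=40, frac_true=0.0, seed=734,
        endpoint_types=("survival",),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_cohort():
    """300 samples, 10 features, 2 strong true targets (HR = 4, delta = 4)."""
    cfg = SimulationConfig(
        n_samples=300, n_features=10, frac_true=0.2, hazard_ratio=4.0,
        mixture_delta=4.0, seed=42, endpoint_types=("survival", "metastasis"),
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
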