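"""Shared fixtures.

The heavy session fixtures (Monte Carlo development dataset, trained
surrogate, scaling study, closed-loop stO2 study) implement the package's
reference desk-scale experiment design and are shared by the acceptance
tests; unit tests only use the lightweight fixtures.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

SEED = 1


@pytest.fixture(scope="session")
def table():
    from tissuelight.optics import load_default_chromophore_table

    return load_default_chromophore_table()


@pytest.fixture(scope="session")
def mc_dataset():
    """Single-wavelength MC development dataset (desk-scale reference size)."""
    from tissuelight.pipelines import generate_single_wavelength_dataset

    return generate_single_wavelength_dataset(6144, 1024, seed=SEED)


@pytest.fixture(scope="session")
def dev_surrogate(mc_dataset):
    from tissuelight.pipelines import train_development_surrogate

    return train_development_surrogate(mc_dataset, seed=SEED)


@pytest.fixture(scope="session")
def scaling_result(mc_dataset):
    from tissuelight.pipelines import scaling_study

    return scaling_study(mc_dataset, seed=SEED)


@pytest.fixture(scope="session")
def closed_loop(dev_surrogate):
    from tissuelight.pipelines import closed_loop_sto2_study

    return closed_loop_sto2_study(dev_surrogate.model, seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_surrogate():
    """Small surrogate trained on an analytic logistic map (fast, no MC)."""
    from tissuelight.surrogate import SurrogateSpec, TrainingConfig, train_surrogate

    rng = np.random.default_rng(7)
    n = 4000
    x = np.column_stack([
        10 ** rng.uniform(-1, 2, n),   # mu_a-like, log-scaled feature
        10 ** rng.uniform(1, 2.5, n),  # mu_s-like
        rng.uniform(0.5, 0.95, n),     # g
        rng.uniform(1.3, 1.5, n),      # n
        10 ** rng.uniform(0.5, 1.5, n),  # d
    ])
    z = (np.log10(x[:, 0]) - 0.5) * 1.2 - (x[:, 2] - 0.7) * 3.0 \
        + (np.log10(x[:, 1]) - 1.7) * 0.8
    y = 1.0 / (1.0 + np.exp(-z))
    spec = SurrogateSpec(input_dim=5, hidden_units=64, hidden_layers=3)
    cfg = TrainingConfig(seed=7, batch_size=128, patience=40, max_epochs=2500,
                         learning_rate=3e-3)
    model = train_surrogate(x[:3200], y[:3200], x[3200:3600], y[3200:3600], spec, cfg)
    return model, x, y
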