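import numpy as np
import pytest

from econn import TimeSeriesMatrix, zero_input
from econn.simulator import InputSpec, NetworkModel, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240930)


@pytest.fixture
def small_ts(rng):
    """12 frames x 3 regions of white noise."""
    return TimeSeriesMatrix(rng.standard_normal((12, 3)), ("V1", "V2", "V3"))


@pytest.fixture
def toy_regression(rng):
    """n=50, p=5 full-rank regression with known coefficients, noise sd 0.1."""
    n, p = 50, 5
    X = rng.standard_normal((n, p))
    beta = np.array([1.5, -2.0, 0.0, 0.7, 3.0])
    y = 0.4 + X @ beta + 0.1 * rng.standard_normal(n)
    return X, y, 0.4, beta


@pytest.fixture
def three_region_sim():
    """Seeded 3-region simulated dataset with a known sparse truth."""
    model = NetworkModel(
        n_regions=3,
        max_lag=2,
        ar_coeffs={(1, 1, 1): 0.4, (2, 2, 1): 0.3, (3, 3, 1): 0.3, (1, 2, 2): 0.35},
        input_coeffs={(1, 1, 1): 0.9, (2, 2, 1): 0.8, (3, 3, 1): 0.7},
        intercepts=(0.0, 0.0, 0.0),
        noise_sd=0.5,
        input_specs=(
            InputSpec("sinusoid", 6, 1.0, 0.2),
            InputSpec("sinusoid", 9, 1.0, 1.0),
            InputSpec("sinusoid", 13, 1.0, 2.2),
        ),
        n_frames=120,
        burn_in=50,
        seed=7,
    )
    ts, u, truth = simulate(model)
    return model, ts, u, truth


@pytest.fixture
def resting_design(small_ts):
    """1-region, zero-input convenience pieces for edge cases."""
    return small_ts, zero_input(small_ts)
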