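import numpy as np
import pytest

from refcast import MonthlySeries, SeriesGeneratorConfig, generate_monthly_series


@pytest.fixture(scope="session")
def referral_series() -> MonthlySeries:
    """An 89-month synthetic referral series with trend + yearly seasonality."""
    return generate_monthly_series(SeriesGeneratorConfig(seed=12345))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def simulate_ar1(n: int, phi: float, rng: np.random.Generator,
                 mu: float = 0.0, sigma: float = 1.0) -> np.ndarray:
    """Exact AR(1) draw with stationary initial condition."""
    x = np.empty(n)
    x[0] = mu + rng.normal(0, sigma / np.sqrt(1 - phi**2))
    e = rng.normal(0, sigma, n)
    for t in range(1, n):
        x[t] = mu + phi * (x[t - 1] - mu) + e[t]
    return x
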