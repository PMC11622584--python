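import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from semenmeth import SimulationConfig, simulate_cohort, simulate_reference

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def semen_cohort():
    """Default semen-like synthetic cohort (binomial noise at 74x)."""
    cfg = SimulationConfig(seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_reference():
    """A 4-cell-type reference methylome on 2000 synthetic sites."""
    return simulate_reference(SimulationConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def planted_cohort():
    """Cohort with strong planted age effects and Gaussian noise.

    Slope 0.1 over the age range against noise sd 0.03 gives a
    slope-to-noise ratio above 3 at 300 planted sites.
    """
    cfg = SimulationConfig(
        n_samples=80,
        seed=3,
        noise_model="gaussian",
        gaussian_sd=0.03,
        n_age_sites=300,
        age_slope=0.1,
        age_frac_negative=0.6,
        n_batch_sites=50,
    )
    return simulate_cohort(cfg)


def make_matrix(values, samples=None, sites=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = samples or [f"S{i:02d}" for i in range(n)]
    sites = sites or [f"chr1:{100 + 10 * j}" for j in range(p)]
    return pd.DataFrame(values, index=samples, columns=sites)
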