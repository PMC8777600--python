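import numpy as np
import pytest

from ginkgoscreen import (
    DEFAULT_GRID,
    CohortConfig,
    Spectrum,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spectrum(rng, grid=DEFAULT_GRID, label=""):
    return Spectrum(grid, rng.normal(0.0, 1.0, grid.n_points), label)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """One product per archetype, no jitter, no noise: exact mixture algebra."""
    counts = {
        "authentic": 1,
        "rutin_adulterated": 1,
        "quercetin_adulterated": 1,
        "quercetin_kaempferol_adulterated": 1,
        "no_ginkgo": 1,
    }
    return simulate_cohort(counts, CohortConfig(noise_sigma=0.0, jitter=0.0), seed=0)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The archetype-discrimination cohort: 4 products each of three
    archetypes at the default noise level."""
    counts = {
        "rutin_adulterated": 4,
        "quercetin_adulterated": 4,
        "no_ginkgo": 4,
    }
    return simulate_cohort(counts, CohortConfig(noise_sigma=0.002), seed=1)
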