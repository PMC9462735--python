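import numpy as np
import pytest

from purebeta import simulate_cohort


@pytest.fixture
def two_pop_xy():
    """Well-separated two-population regression data with ground truth.

    Population A: y = 0.0 + 0.9 x; population B: y = 0.9 + 0.0 x;
    residual SD 0.03, x ~ Uniform(0.1, 0.8), n = 200.
    """
    rng = np.random.default_rng(2024)
    n = 200
    labels = rng.integers(0, 2, size=n)
    x = rng.uniform(0.1, 0.8, size=n)
    y = np.where(labels == 0, 0.0 + 0.9 * x, 0.9 + 0.0 * x)
    y = y + rng.normal(0.0, 0.03, size=n)
    return y, x, labels


@pytest.fixture
def brca1_like():
    """Promoter-hypermethylation geometry: a hypermethylated minority whose
    beta rises with purity, an unmethylated majority, shared normal
    background 0.1; 235 samples, purity ~ Uniform(0.2, 0.9), SD 0.03."""
    rng = np.random.default_rng(99)
    n = 235
    purity = rng.uniform(0.2, 0.9, size=n)
    hyper = rng.random(n) < 0.3
    tumor_state = np.where(hyper, 1.0, 0.0)
    normal_state = 0.1
    beta = purity * tumor_state + (1.0 - purity) * normal_state
    beta = np.clip(beta + rng.normal(0.0, 0.03, size=n), 0.0, 1.0)
    return beta, purity, hyper, normal_state


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed-K cohort reused across recovery tests."""
    return simulate_cohort(
        n_samples=120,
        n_cpgs=40,
        k_probs={1: 0.5, 2: 0.5},
        noise_sd=0.03,
        state_levels=(0.0, 0.5, 1.0),
        normal_levels=(0.0, 0.3, 0.7),
        seed=7,
    )
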