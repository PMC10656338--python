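import numpy as np
import pytest

from wpvscausal import DgpSpec, apply_centering, simulate_panel


@pytest.fixture(scope="session")
def default_sim():
    """One moderate default-condition panel shared by read-only tests."""
    return simulate_panel(DgpSpec(N=2000, K=4, phi2=10.0, seed=42))


@pytest.fixture(scope="session")
def true_scores(default_sim):
    return apply_centering(default_sim, "true_score")


@pytest.fixture(scope="session")
def model_true_series():
    """Data generated from the measurement model itself: stable trait of
    variance 10 plus a stationary AR(1) within process (lag coefficient
    0.5, stationary variance 10), N=5000, five waves."""
    rng = np.random.default_rng(314)
    n_persons, n_waves, a, var = 5000, 5, 0.5, 10.0
    innov = var * (1 - a * a)
    within = np.zeros((n_persons, n_waves))
    within[:, 0] = rng.normal(0, np.sqrt(var), n_persons)
    for k in range(1, n_waves):
        within[:, k] = a * within[:, k - 1] + rng.normal(
            0, np.sqrt(innov), n_persons
        )
    trait = rng.normal(0, np.sqrt(10.0), n_persons)
    return {
        "data": within + trait[:, None],
        "within": within,
        "trait": trait,
        "a": a,
        "var": var,
        "innov": innov,
        "phi2": 10.0,
    }
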