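import numpy as np
import pytest

from metacfa.fit_engine import prepare_data
from metacfa.simulation import SimCondition, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated meta-analytic dataset under strong-invariance truth
    (30 studies, n=100 within)."""
    cond = SimCondition(invariance_truth="strong", k_per_group=15, n_within=100,
                        reps=1, seed=42)
    return generate_dataset(cond, 0)


@pytest.fixture(scope="session")
def small_prep(small_dataset):
    return prepare_data(small_dataset)


@pytest.fixture(scope="session")
def fitted_ladder(small_prep):
    """Saturated/configural/weak/strong fits on the shared dataset."""
    from metacfa.fit_engine import FitOptions, fit_invariance_ladder
    from metacfa.simulation import base_spec

    return fit_invariance_ladder(
        base_spec(), "group", small_prep,
        options=FitOptions(compute_se=False),
    )
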