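import numpy as np
import pytest

from pshazard.datagen import (OutcomeModel, TreatmentModel,
                              calibrate_treatment_intercept, simulate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20121212)


def random_survival_data(rng, n=40, p=1, beta=None, rate=0.01):
    """Small uncensored survival dataset with known covariate effects."""
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.linspace(0.5, -0.5, p)
    T = -np.log(rng.random(n)) / (rate * np.exp(X @ np.atleast_1d(beta)))
    E = np.ones(n, dtype=int)
    return T, E, X


@pytest.fixture
def paper_cohort(rng):
    """One reference-design cohort: 25% treated, conditional HR e^0.8."""
    a0 = calibrate_treatment_intercept(0.25)
    return simulate_cohort(4000, TreatmentModel(a0), OutcomeModel(0.8), rng)
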