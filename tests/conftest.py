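import numpy as np
import pandas as pd
import pytest

from iiwbias import OutcomeModelSpec, VisitModelSpec, simulate_cohort
from iiwbias.experiments import mc_gamma_bias_oracle


@pytest.fixture(scope="session")
def bernoulli_oracle():
    """Monte-Carlo gamma-hat bias, time-invariant Bernoulli(0.5) Z.

    Shared across the intensity consistency check and the closed-form
    agreement check: 200 replicates of n=5000 subjects with Poisson visit
    counts at gamma0=0.5, Lambda0=1.
    """
    return mc_gamma_bias_oracle(
        ("bernoulli", 0.5), gamma0=0.5, lambda0=0.5, tau=2.0,
        n=5000, n_reps=200, seed=907,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mechanism-1 cohort reused by structural tests."""
    return simulate_cohort(
        120, OutcomeModelSpec(mechanism=1), VisitModelSpec(), seed=321
    )


@pytest.fixture
def cox_fixture_rows():
    """Three-subject worked example with binary time-invariant Z.

    A (Z=1) has events at 0.5 and 1.5; B (Z=0) at 1.0; C (Z=0) none;
    tau=2.  The partial-likelihood score has closed-form roots:
    gamma = log 4 with everyone, log 2 after dropping C.
    """
    return pd.DataFrame(
        {
            "subject_id": ["A", "A", "A", "B", "B", "C"],
            "start": [0.0, 0.5, 1.5, 0.0, 1.0, 0.0],
            "stop": [0.5, 1.5, 2.0, 1.0, 2.0, 2.0],
            "event": [1, 1, 0, 1, 0, 0],
            "z": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2718)
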