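import numpy as np
import pytest

import ordtrend as ot


@pytest.fixture(scope="session")
def scheme():
    return ot.who_bmi_scheme()


@pytest.fixture(scope="session")
def diabetes():
    table, scheme = ot.load_diabetes_table()
    return table, scheme


@pytest.fixture(scope="session")
def blood_pressure():
    table, scheme = ot.load_blood_pressure_table()
    return table, scheme


@pytest.fixture(scope="session")
def population():
    """Synthetic BMI population shared by the simulation tests."""
    rng = np.random.default_rng(20260921)
    return ot.make_synthetic_population(ot.default_spec(), 20000, rng)


def random_estimates(rng, r=4, ref=1, outcome_kind="binary"):
    """Non-degenerate random per-class effect estimates (WHO medians)."""
    theta = np.exp(rng.normal(0.0, 0.8, r))
    var = np.exp(rng.normal(-3.0, 0.7, r))
    n = rng.integers(20, 3000, r).astype(float)
    m_star = np.array([17.0, 23.0, 28.0, 35.0])[:r] - 23.0
    theta[ref] = 1.0
    var[ref] = 0.0
    return ot.EffectEstimates(
        theta=theta,
        var_log_theta=var,
        n=n,
        m_star=m_star,
        reference_index=ref,
        outcome_kind=outcome_kind,
    )
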