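import numpy as np
import pandas as pd
import pytest

from rwediag import simulate_patient_level_study
from rwediag.simulate import legend_like_scenario, simulate_estimate_set


@pytest.fixture(scope="session")
def small_study():
    """A moderately confounded patient-level cohort reused across tests."""
    return simulate_patient_level_study(
        n_patients=5000,
        m_covariates=3,
        confounding_strength=1.0,
        n_negative_controls=4,
        seed=20_260_901,
    )


@pytest.fixture(scope="session")
def legend_system():
    """Evidence system with diagnostic-correlated mixture bias (2000 analyses)."""
    scenario = legend_like_scenario(n_analyses=2000, seed=20_260_902)
    return simulate_estimate_set(scenario)


def make_controls(n, mu, tau, seed, se_low=0.05, se_high=0.2):
    """Negative-control estimates drawn directly from the convolution model
    theta_i ~ Normal(mu, tau^2 + s_i^2) — the oracle-side generator used to
    test fit_null independently of simulate_estimate_set."""
    rng = np.random.default_rng(seed)
    se = rng.uniform(se_low, se_high, size=n)
    theta = rng.normal(mu, np.sqrt(tau**2 + se**2))
    return pd.DataFrame({"log_rr": theta, "se_log_rr": se})
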