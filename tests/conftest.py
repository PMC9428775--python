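import numpy as np
import pytest

from actimediate import AnalysisSpec, TrialConfig
from actimediate.synthetic import simulate_analysis_table, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_trial():
    """A compact but complete simulated trial (4+4 schools, 6 days)."""
    cfg = TrialConfig(
        n_schools_per_arm=4,
        participants_per_school=8,
        days_per_time_point=6,
        seed=42,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def analysis_table():
    """Default-dimension analysis table with known generating values."""
    cfg = TrialConfig(
        a_true={"barriers": 2.5},
        b_true={("barriers", "sedentary"): 0.8},
        seed=77,
    )
    table, truth = simulate_analysis_table(cfg)
    return table, truth


@pytest.fixture
def ols_spec():
    return AnalysisSpec(cluster_var=None, seed=0)
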