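import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_bundle():
    """Small synthetic scenario with stochastic TCs and delayed release."""
    from gbmrisk import SyntheticScenarioSpec, make_scenario

    return make_scenario(SyntheticScenarioSpec(
        n_runs=300, seed=42, tc_spread=0.08, production_cv=0.5,
        use_release_fraction=0.5, horizon_years=8))


@pytest.fixture
def hazard_bundle():
    from gbmrisk import SyntheticHazardSpec, make_hazard_dataset

    return make_hazard_dataset(SyntheticHazardSpec(seed=7))
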