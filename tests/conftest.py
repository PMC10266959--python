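import pytest

from ionapath import ScenarioParams, default_config, expected_case_mix
from ionapath.pipeline import calibrated_rates


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture(scope="session")
def base_probs(base_config):
    return base_config.arm_probabilities()


@pytest.fixture(scope="session")
def base_calibration(base_config):
    """(probs, rates, calibration, current_mix, proposed_mix) at N = 198."""
    return calibrated_rates(base_config)


@pytest.fixture(scope="session")
def base_rates(base_calibration):
    return base_calibration[1]


@pytest.fixture(scope="session")
def base_mixes(base_probs):
    current = expected_case_mix(198.0, base_probs, ScenarioParams.current())
    proposed = expected_case_mix(198.0, base_probs, ScenarioParams.proposed())
    return current, proposed
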