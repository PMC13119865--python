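import numpy as np
import pytest

import copdcue


@pytest.fixture(scope="session")
def default_params():
    return copdcue.load_config()


@pytest.fixture()
def params(default_params):
    """Mutable copy of the shipped defaults."""
    return default_params.copy()


@pytest.fixture(scope="session")
def model(default_params):
    return copdcue.CostUtilityModel(default_params)


def randomize_params(params, rng: np.random.Generator):
    """Perturb every sampled item and tree split to a random valid value."""
    for item in params.costs.values():
        item.mean = float(rng.uniform(1.0, 2000.0))
    for item in params.probabilities.values():
        item.mean = float(rng.uniform(0.05, 0.95))
    for key in ("partially_recovered", "fully_recovered",
                "stage_2", "stage_3", "stage_4"):
        params.utilities[key].value = float(rng.uniform(0.3, 0.95))
    params.tree["second_line_ae_split"] = float(rng.uniform(0.0, 1.0))
    params.tree["p_bacterial_control"] = float(rng.uniform(0.0, 1.0))
    params.tree["full_recovery_after_admission"] = float(rng.uniform(0.0, 1.0))
    return params
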