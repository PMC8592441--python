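import copy

import pytest

import sclc_cea as sc

#: Fitted log-logistic (theta, gamma) per arm and endpoint, time in 21-day cycles.
ARM_PARAMS = {
    ("pembro_ep", "os"): (0.008564, 1.719092),
    ("placebo_ep", "os"): (0.002564, 2.260147),
    ("pembro_ep", "pfs"): (0.007161, 2.510618),
    ("placebo_ep", "pfs"): (0.000417, 4.150059),
}


def loglogistic(arm, endpoint):
    return sc.SurvivalParams("loglogistic", ARM_PARAMS[(arm, endpoint)])


@pytest.fixture(scope="session")
def base_config():
    return sc.make_base_case_config()


@pytest.fixture
def fresh_config(base_config):
    return copy.deepcopy(base_config)


@pytest.fixture(scope="session")
def base_result(base_config):
    return sc.evaluate(base_config)


@pytest.fixture(scope="session")
def psa_draws(base_config):
    return sc.run_psa(base_config, seed=20260901)
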