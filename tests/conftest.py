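import dataclasses

import pytest
from hypothesis import settings

import helifret as hf

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def wt_params():
    return hf.preset_params("wild_type")


@pytest.fixture(scope="session")
def wt_condition():
    return hf.Condition()  # 40 nM RHA, 1 mM ATP, RT, 50% GC


@pytest.fixture(scope="session")
def noiseless_params(wt_params):
    return dataclasses.replace(wt_params, sigma_noise=0.0)


@pytest.fixture(scope="session")
def wt_dataset(wt_params, wt_condition):
    """Shared wild-type dataset at default conditions (seeded)."""
    return hf.simulate_dataset(wt_params, [wt_condition], 100, 250.0, 314)


@pytest.fixture(scope="session")
def wt_dwell_table(wt_dataset, wt_condition):
    key = wt_condition.key()
    return hf.analyze_traces(wt_dataset.traces[key], condition_key=key)
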