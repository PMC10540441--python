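import numpy as np
import pytest

from semiogram import GaitTrialModel, simulate


@pytest.fixture(scope="session")
def healthy_spec():
    return simulate.WalkerSpec(seed=7)


@pytest.fixture(scope="session")
def healthy_trial(healthy_spec):
    trial, truth = simulate.generate_trial(healthy_spec)
    return trial, truth


@pytest.fixture(scope="session")
def healthy_results(healthy_trial):
    trial, _ = healthy_trial
    return GaitTrialModel(trial).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
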