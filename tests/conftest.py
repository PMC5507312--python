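import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myoenergetics.datatypes import AcquisitionParams, ProtocolSpec
from myoenergetics.synthetic import (TruthParams, simulate_dynamic_timecourse,
                                     simulate_fully_relaxed)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth() -> TruthParams:
    return TruthParams()


@pytest.fixture(scope="session")
def protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def relaxed_noiseless(truth):
    return simulate_fully_relaxed(truth, AcquisitionParams.fully_relaxed(),
                                  snr=np.inf)


@pytest.fixture(scope="session")
def dynamic_noiseless(truth, protocol):
    return simulate_dynamic_timecourse(truth, protocol, snr=np.inf)


@pytest.fixture(scope="session")
def noiseless_experiment(truth):
    """Full noiseless spectroscopy chain, shared across tests."""
    from myoenergetics.pipeline import quantify_experiment
    return quantify_experiment(truth, noiseless=True)
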