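import numpy as np
import pytest

from rbcmech import ProtocolSpec, SLSParams, simulate_relaxation_curve


@pytest.fixture(scope="session")
def default_params() -> SLSParams:
    """Instrument-scale SLS parameters used throughout the suite."""
    return SLSParams(k1=0.02, k2=0.01, f=0.002, kc=0.03)


@pytest.fixture(scope="session")
def default_protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def clean_relaxation(default_params, default_protocol):
    """One noiseless relaxation curve plus its ground truth."""
    return simulate_relaxation_curve(default_params, default_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
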