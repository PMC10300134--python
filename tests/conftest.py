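import numpy as np
import pytest

from promkin.fitting import CellTrace, FitConfig
from promkin.model import InductionProtocol, KineticParams, integrate_model


@pytest.fixture(scope="session")
def central_params() -> KineticParams:
    """GAL1pr-like central parameters used throughout the synthetic tests."""
    return KineticParams(b=1e-4, i=1e-3, f=0.035, d=0.017, t_on=10.0, t_off=5.0)


@pytest.fixture(scope="session")
def protocol() -> InductionProtocol:
    return InductionProtocol()


@pytest.fixture(scope="session")
def noiseless_trace(central_params, protocol) -> CellTrace:
    """Exact model trace on the canonical sampling grid."""
    times = protocol.times()
    return CellTrace("noiseless", times, integrate_model(central_params, protocol, times))


@pytest.fixture(scope="session")
def fit_config() -> FitConfig:
    """Staged-fit settings for synthetic data (no media transport delay)."""
    return FitConfig(chemically_induced=False)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
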