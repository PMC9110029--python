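import numpy as np
import pytest

from sectransport.kinetic_model import AssayConditions, RateParameters
from sectransport.synthetic_data import LXX_PARAMS, TraceGenSpec, make_trace_dataset


@pytest.fixture(scope="session")
def baseline_params() -> RateParameters:
    """Published baseline-construct kinetics (6 steps at 5.31 min^-1)."""
    return LXX_PARAMS


@pytest.fixture(scope="session")
def default_conditions() -> AssayConditions:
    return AssayConditions()


@pytest.fixture(scope="session")
def baseline_traces(baseline_params):
    """12 replicate traces at the baseline parameters, 1% noise."""
    spec = TraceGenSpec(params=baseline_params, noise_sd=0.01, replicates=12, seed=42)
    return make_trace_dataset(spec)


@pytest.fixture(scope="session")
def saturating_params():
    """No failure/blocking, effectively irreversible saturating binding."""
    def _make(n, k_step):
        return RateParameters(n=n, k_step=k_step, k_fail=0.0, k_block=0.0,
                              k_on=1e6, k_off=0.0)
    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
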