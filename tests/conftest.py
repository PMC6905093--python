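import pytest
from hypothesis import settings

from neutrogame import (
    DataFitConstants,
    ParameterTuple,
    bc_sum_from_constraints,
    n_from_m,
)

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def constants() -> DataFitConstants:
    return DataFitConstants()


@pytest.fixture(scope="session")
def data_tuple(constants) -> ParameterTuple:
    """A data-consistent tuple anchored at alpha = 1.0, m = 0.0015."""
    alpha, m = 1.0, 0.0015
    bc = bc_sum_from_constraints(alpha, m, constants)
    return ParameterTuple(
        alpha=alpha,
        b_apoptosis=0.4 * bc,
        c_necrosis=0.6 * bc,
        m=m,
        n=n_from_m(m, constants),
    )
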