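import numpy as np
import pytest

from spikebench import MODEL_NAMES, SimulationGrid, make_model


@pytest.fixture
def grid():
    return SimulationGrid(dt=0.1)


@pytest.fixture
def bench_models():
    """All nine models configured from the benchmark regime."""
    return {name: make_model(name, params_source="table3") for name in MODEL_NAMES}


@pytest.fixture
def trace_models():
    """All nine models configured from the trace regime."""
    return {name: make_model(name, params_source="table2") for name in MODEL_NAMES}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
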