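import numpy as np
import pytest

from poolskim import (
    PoolCallerConfig,
    ReferenceLocus,
    SamplingDesign,
    SequencingModel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def small_design():
    """Two regions x two catchments, one site per catchment, pools of 8."""
    return SamplingDesign(
        regions=("north", "south"),
        catchments={"n1": "north", "n2": "north", "s1": "south", "s2": "south"},
        sites={"N1a": "n1", "N2a": "n2", "S1a": "s1", "S2a": "s2"},
        pool_size=8,
    )


@pytest.fixture
def default_design():
    return SamplingDesign.default()


@pytest.fixture
def small_locus():
    return ReferenceLocus.random("cpDNA", 2_000, seed=7)


@pytest.fixture
def caller_config():
    return PoolCallerConfig()


@pytest.fixture
def clean_model():
    return SequencingModel(mean_depth=60.0, error_rate=0.0)
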