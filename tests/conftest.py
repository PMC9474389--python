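import numpy as np
import pytest

import phasetree as pt


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def yule_model():
    """Pure-birth model with unit speciation rate."""
    return pt.WaitingTimeModel(speciation=("exponential", {"rate": 1.0}))


@pytest.fixture
def toy_branchdata():
    """One internal branch of length 1, two pendant branches of length 1."""
    return pt.BranchData(
        internal=np.array([1.0]),
        pendant=np.array([1.0, 1.0]),
        x=np.array([1.0]),
        age=2.0,
        x2=2.0,
    )
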