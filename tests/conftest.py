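import pytest

import physiomap as pm
from physiomap import fixtures as fx


@pytest.fixture(scope="session")
def registry():
    return pm.load_registry()


@pytest.fixture
def glycolysis():
    """(model, declared-counts spec) for the toy glycolysis chain."""
    return fx.make_glycolysis_toy()


@pytest.fixture
def cv4():
    """(model, spec) for the 4-compartment cardiovascular ring."""
    return fx.make_cv_circuit(4)
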