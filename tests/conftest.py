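import pytest

from birscreen.synthetic_data import build_library, build_reference_panel
from birscreen.switch_caller import PanelIndex


@pytest.fixture(scope="session")
def panel():
    """One CTG-repeat reference panel shared across the suite."""
    return build_reference_panel(seed=11)


@pytest.fixture(scope="session")
def panel_index(panel):
    return PanelIndex(panel)


@pytest.fixture(scope="session")
def small_library():
    """A compact library: 40 genes plus the full control complement."""
    return build_library(n_genes=40, seed=3)
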