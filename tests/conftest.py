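import numpy as np
import pytest

from fruitlab.panel import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One reference synthetic panel shared across read-only tests."""
    return generate_panel(PanelConfig(seed=123))


@pytest.fixture(scope="session")
def small_panel():
    """A 60-accession panel for faster pipeline-level tests."""
    return generate_panel(PanelConfig(n_accessions=60, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
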