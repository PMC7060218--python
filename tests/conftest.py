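import numpy as np
import pytest

from pkdscreen import ScreenConfig, make_truth_table, simulate_monolayer_screen
from pkdscreen.normalize import assemble_titrations, normalize_wells


@pytest.fixture(scope="session")
def small_truth():
    return make_truth_table(60, seed=11)


@pytest.fixture(scope="session")
def clean_screen(small_truth):
    """Zero-noise 60-compound monolayer screen plus its normalized wells."""
    cfg = ScreenConfig(n_compounds=60, noise_cv=0.0, n_replicates=1, seed=11)
    wells = simulate_monolayer_screen(cfg, small_truth)
    return cfg, wells, normalize_wells(wells)


@pytest.fixture(scope="session")
def clean_titrations(clean_screen):
    _, _, normalized = clean_screen
    return assemble_titrations(normalized)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
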