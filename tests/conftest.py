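import pytest

import mentkin as mk


@pytest.fixture(scope="session")
def small_config():
    """Reduced crossed design: 4 participants per cell, 2 animations per
    word x generator-cell (48 rated animations per observer)."""
    return mk.DesignConfig(n_per_cell=4, animations_per_cell=2, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return mk.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_tables(small_study):
    return mk.build_tables(small_study)


@pytest.fixture(scope="session")
def default_study():
    """A study at the full crossed-design defaults (15 per cell, 144 rated
    animations per observer)."""
    return mk.simulate_study(mk.DesignConfig(n_per_cell=15, seed=7))
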