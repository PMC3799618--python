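import numpy as np
import pytest

from deforsim import (FOREST, DEFORESTED, EXCLUDED, GridMeta, LandscapeState,
                      Layer, SyntheticScenario, make_landscape)


@pytest.fixture(scope="session")
def scene40():
    """A small reproducible synthetic landscape shared across tests."""
    return make_landscape(SyntheticScenario(n_rows=40, n_cols=40, seed=7))


@pytest.fixture
def meta3():
    return GridMeta(n_rows=3, n_cols=3, cell_size=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_state(meta: GridMeta, rng: np.random.Generator,
                 p_def: float = 0.2, p_exc: float = 0.1,
                 year: int = 0) -> LandscapeState:
    """Random land-cover state with all three codes present."""
    u = rng.random(meta.shape)
    state = np.full(meta.shape, FOREST, dtype=np.int8)
    state[u < p_def] = DEFORESTED
    state[u > 1 - p_exc] = EXCLUDED
    return LandscapeState(meta=meta, state=state, year=year)
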