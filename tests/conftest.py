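import numpy as np
import pytest

from impact_atlas.grid import GridSpec, Layer, Semantics


@pytest.fixture
def spec3():
    return GridSpec(3, 3)


def make_layer(values, valid=None, semantics=Semantics.IMPACT):
    """2-D list with None for missing cells -> Layer."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    return Layer.from_values(arr, valid=valid, semantics=semantics)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_layer(rng, nrows=10, ncols=10, invalid_frac=0.2, semantics=Semantics.IMPACT):
    values = rng.lognormal(0.0, 1.0, size=(nrows, ncols))
    valid = rng.random((nrows, ncols)) >= invalid_frac
    return Layer(GridSpec(nrows, ncols), values, valid, semantics)
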