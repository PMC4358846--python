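import numpy as np
import pytest

from mfdfa2d import FeatureTable, ScaleGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_surface(rng):
    """A 64x64 noise surface, gray levels in (0, 255)."""
    return rng.random((64, 64)) * 255.0


@pytest.fixture
def small_scale_grid():
    return ScaleGrid((6, 8, 10, 12, 16))


@pytest.fixture
def two_species_table():
    """Two species with hand-computable spread: values {1,2,3} vs {7,8,9}.

    The first feature carries the shift; the others are copies so the
    table stays 12 columns wide.
    """
    vals = np.tile(np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])[:, None], (1, 12))
    return FeatureTable(
        [f"a{i}" for i in range(6)],
        ["A", "A", "A", "B", "B", "B"],
        vals,
    )
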