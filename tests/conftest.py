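import numpy as np
import pytest

from scenestats.image_features import EdgeMap, FEATURE_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_edge_map(shape, weight_coords, gradients=None, weights=None):
    """Construct an EdgeMap directly from pixel coordinates.

    ``weight_coords`` is a list of (rows, cols, weight, gx, gy) tuples;
    gradients default to a vertical-gradient edge (gy=1, gx=0).
    """
    H, W = shape
    w = np.zeros(shape)
    gx = np.zeros(shape)
    gy = np.zeros(shape)
    for rows, cols, weight, gxv, gyv in weight_coords:
        w[rows, cols] = weight
        gx[rows, cols] = gxv
        gy[rows, cols] = gyv
    return EdgeMap(w, gx, gy, (0.1, 0.2), (0.2, 0.4))


@pytest.fixture
def feature_table_columns():
    return list(FEATURE_NAMES)
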