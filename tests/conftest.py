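import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from aznano.locio import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_roi():
    """A 200-nm-radius circular active-zone polygon."""
    return Point(0.0, 0.0).buffer(200.0, quad_segs=64)


def make_table(
    x, y, frame=None, photons=None, sigma=None, precision=None,
    pixel_size_nm=160.0, n_frames=30000, target_id="t",
) -> LocalizationTable:
    x = np.asarray(x, float)
    n = len(x)
    df = pd.DataFrame(
        {
            "x_nm": x,
            "y_nm": np.asarray(y, float),
            "frame": np.zeros(n, int) if frame is None else np.asarray(frame, int),
            "photons": np.full(n, 1000.0) if photons is None else np.asarray(photons, float),
            "sigma_px": np.full(n, 1.0) if sigma is None else np.asarray(sigma, float),
            "precision_nm": np.full(n, 8.0) if precision is None else np.asarray(precision, float),
        }
    )
    return LocalizationTable(df, pixel_size_nm=pixel_size_nm, n_frames=n_frames, target_id=target_id)


@pytest.fixture
def table_factory():
    return make_table
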