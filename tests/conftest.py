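import numpy as np
import pandas as pd
import pytest

from dsbquant import smlm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_roi():
    """10 x 10 um square nucleus ROI (polygon representation)."""
    return smlm.roi_from_polygon(
        [(0, 0), (10_000, 0), (10_000, 10_000), (0, 10_000)], nucleus_id="sq"
    )


def make_table(x, y, channel="A", nucleus_id="n0"):
    x = np.asarray(x, float)
    return pd.DataFrame(
        {
            "nucleus_id": nucleus_id,
            "channel": channel,
            "x": x,
            "y": np.asarray(y, float),
            "frame": np.arange(len(x)),
        }
    )
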