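import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cetamove.io_formats import ArgosObservation

UTC = dt.timezone.utc


def make_obs(ts, lon, lat, qc="2", smaj=None, smin=None, orient=None):
    return ArgosObservation(
        timestamp=ts, lon=lon, lat=lat, quality_class=qc,
        ellipse_semi_major=smaj, ellipse_semi_minor=smin,
        ellipse_orientation=orient,
    )


@pytest.fixture
def t0():
    return dt.datetime(2019, 1, 8, tzinfo=UTC)


@pytest.fixture
def straight_track(t0):
    """Slow straight northward track, hourly fixes (no outliers)."""
    obs = []
    for i in range(10):
        # 0.3 m/s northward: ~1080 m per hour ~ 0.00977 deg lat
        obs.append(make_obs(t0 + dt.timedelta(hours=i), -20.0, 45.0 + i * 0.00977))
    return obs


@pytest.fixture
def regular_track_frame(t0):
    """Regular 6-hourly planar track frame (x, y in metres)."""
    n = 60
    ts = pd.date_range(t0, periods=n, freq="6h")
    x = np.linspace(0, 59 * 1.5 * 21600, n)       # 1.5 m/s east
    y = np.zeros(n)
    return pd.DataFrame({"timestamp": ts, "x": x, "y": y,
                         "lon": -20 + x / 78800.0, "lat": np.full(n, 45.0)})
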