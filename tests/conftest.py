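"""Shared fixtures: hand-built streams, geometry, and small AOI tracks."""

import numpy as np
import pandas as pd
import pytest

from socialgaze.aoi import AoiShape, AoiTrack
from socialgaze.events import GEOMETRY_17IN_1280x1024
from socialgaze.gaze_io import GazeStream

DT = 1000.0 / 60.0


@pytest.fixture
def geom():
    return GEOMETRY_17IN_1280x1024


def make_stream(points, start_ms=0, validity=None, recording_id="test"):
    """Stream from (x, y) points at nominal 60 Hz spacing.

    ``validity`` is an optional per-sample iterable of codes applied to both
    eyes (default all 0); NaN coordinates are allowed for invalid samples.
    """
    n = len(points)
    times = start_ms + np.round(np.arange(n) * DT).astype(np.int64)
    validity = list(validity) if validity is not None else [0] * n
    frame = pd.DataFrame(
        {
            "time_ms": times,
            "x_px": [p[0] for p in points],
            "y_px": [p[1] for p in points],
            "validity_left": validity,
            "validity_right": validity,
        }
    )
    return GazeStream(frame, recording_id=recording_id)


def static_track(aoi_id, center, size=(110.0, 140.0), t_end=60_000, kind="ellipse"):
    shape = AoiShape(kind, center, size)
    return AoiTrack(aoi_id, ((0, shape), (t_end, shape)))


@pytest.fixture
def stationary_stream():
    """1 s of sub-threshold jitter around (400, 300)."""
    rng = np.random.default_rng(0)
    pts = 400 + rng.normal(0, 1.0, (60, 2))
    return make_stream([(p[0], p[1] - 100) for p in pts])
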