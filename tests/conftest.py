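import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gazesal.geometry import ScreenGeometry
from gazesal.recording import CompositeStream, TrialSegment

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# 24-inch 16:9 panel at 60 cm: the standard fixture geometry
FIXTURE_GEOMETRY = ScreenGeometry(
    width_px=1920, height_px=1080, width_cm=53.1, height_cm=29.9, distance_cm=60.0
)


@pytest.fixture
def geometry() -> ScreenGeometry:
    return FIXTURE_GEOMETRY


@pytest.fixture
def image_rect():
    return (560.0, 140.0, 800.0, 800.0)


@pytest.fixture
def trial(image_rect):
    return TrialSegment("img0", 0.0, 5000.0, image_rect)


def make_stream(positions, dt_ms=2.0, t0=0.0, valid=None) -> CompositeStream:
    """Composite stream from a list of (x, y) pixel positions."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    v = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return CompositeStream(
        t_ms=t0 + dt_ms * np.arange(n),
        x_px=pos[:, 0].copy(),
        y_px=pos[:, 1].copy(),
        valid=v,
    )


def make_samples(xy, dt_ms=2.0) -> pd.DataFrame:
    """Binocular sample frame with both eyes at the given positions."""
    pos = np.asarray(xy, dtype=float)
    n = len(pos)
    return pd.DataFrame(
        {
            "t_ms": dt_ms * np.arange(n),
            "lx": pos[:, 0],
            "ly": pos[:, 1],
            "rx": pos[:, 0],
            "ry": pos[:, 1],
            "lvalid": True,
            "rvalid": True,
        }
    )
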