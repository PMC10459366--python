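from __future__ import annotations

import sys
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from mielapse.sequence_io import Frame

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

T0 = datetime(2022, 6, 1, 8, 0, 0)


def make_frame(image: np.ndarray, k: int = 0, interval_s: float = 30.0) -> Frame:
    """Wrap an array as a frame k intervals after the reference origin."""
    ts = T0 + timedelta(seconds=k * interval_s)
    return Frame(
        image=np.asarray(image, dtype=np.uint8),
        timestamp=ts,
        frame_id=ts.strftime("%Y%m%d-%H%M%S"),
    )


def random_frame_triple(rng: np.random.Generator, h: int, w: int) -> tuple[Frame, Frame, Frame]:
    return tuple(
        make_frame(rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8), k=k)
        for k in range(3)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
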