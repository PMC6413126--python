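import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gaitsym import (
    BENCHMARK_IMAGE_SIZE,
    BENCHMARK_INTRINSICS,
    CameraIntrinsics,
    DepthFrame,
    WalkConfig,
)

#: Small camera for fast simulator tests (quarter Kinect-2 resolution).
TINY_INTRINSICS = CameraIntrinsics(fx=91.25, fy=91.25, cx=64.0, cy=53.0)
TINY_IMAGE_SIZE = (106, 128)


@pytest.fixture
def intrinsics():
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=320.0, cy=240.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_frame(depth_entries, shape=(480, 640), mask="auto"):
    """Frame with listed (row, col, depth_m) entries; mask = valid pixels."""
    depth = np.zeros(shape)
    for r, c, d in depth_entries:
        depth[r, c] = d
    m = depth > 0 if isinstance(mask, str) else mask
    return DepthFrame(depth=depth, mask=m)


def tiny_walk_config(**kw):
    kw.setdefault("camera", TINY_INTRINSICS)
    kw.setdefault("image_size", TINY_IMAGE_SIZE)
    kw.setdefault("n_frames", 13)
    kw.setdefault("noise_sd", 0.0)
    return WalkConfig(**kw)


def benchmark_walk_config(**kw):
    kw.setdefault("camera", BENCHMARK_INTRINSICS)
    kw.setdefault("image_size", BENCHMARK_IMAGE_SIZE)
    return WalkConfig(**kw)
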