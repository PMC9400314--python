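import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import endoquant as eq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def high_snr_config():
    """Bright, well-separated spots: detection should be essentially exact."""
    return eq.SynthImageConfig(spot_intensity=20000.0, seed=42)


@pytest.fixture
def snr10_config():
    """Spot peak roughly 10x the noise sd at the spot (shot + read noise)."""
    return eq.SynthImageConfig(spot_intensity=2000.0, seed=42)


@pytest.fixture
def disk_cell():
    """A geometric disk mask of radius 40 px in a 101x101 frame."""
    yy, xx = np.mgrid[0:101, 0:101]
    mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 40**2
    return eq.CellRegion(
        mask=mask,
        intensity_centroid_px=(50.0, 50.0),
        area_px=int(mask.sum()),
        threshold_value=0.0,
    )


def make_stack(planes, pixel_size_nm=100.0, frame_interval_s=1.0, names=None):
    """Wrap a (T, C, Y, X) array (or a single plane) as a FrameStack."""
    arr = np.asarray(planes, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    return eq.FrameStack(
        data=arr,
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
        channel_names=names or [],
    )
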