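import numpy as np
import pytest

from thermoroi import HotspotSpec, SceneSpec, SearchWindow


@pytest.fixture
def small_scene_spec():
    """Compact two-hotspot scene used across modules (fast to render)."""
    return SceneSpec(
        shape=(140, 200),
        fiducial_centers=((30.0, 40.0), (30.0, 160.0), (110.0, 40.0), (110.0, 160.0)),
        hotspots=(
            # fractional centres: plateaus are not aligned to the pixel grid
            HotspotSpec(center=(70.3, 60.6), semi_axes=(12.0, 16.0), side="left"),
            HotspotSpec(center=(70.3, 140.6), semi_axes=(12.0, 16.0), side="right"),
        ),
        n_frames=3,
        noise_sd_c=0.0,
        seed=11,
    )


@pytest.fixture
def scene_windows():
    return {
        "left": SearchWindow(45, 100, 30, 95, side="left"),
        "right": SearchWindow(45, 100, 110, 175, side="right"),
    }


@pytest.fixture
def plateau_frame_5x5():
    """5x5 frame: 33 °C border ring around a 3x3 plateau at 37 °C."""
    vals = np.full((5, 5), 33.0)
    vals[1:4, 1:4] = 37.0
    return vals
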