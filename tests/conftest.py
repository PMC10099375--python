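import numpy as np
import pytest

from blinkglass import (
    BlinkWaveformParams,
    EyeShapeParams,
    KeypointSet,
    render_eye_frame,
    synth_blink_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def open_eye_keypoints():
    """A plausible open-eye keypoint set inside a 128x128 frame."""
    return KeypointSet(
        np.array(
            [
                [64.0, 24.0],
                [64.0, 104.0],
                [52.0, 50.0],
                [52.0, 78.0],
                [76.0, 50.0],
                [76.0, 78.0],
            ]
        )
    )


@pytest.fixture
def single_blink_recording():
    """Noiseless 12 s recording with one blink at t=5 s."""
    return synth_blink_recording(
        BlinkWaveformParams(blink_times=(5.0,), duration_s=12.0, noise_sd=0.0, seed=0)
    )


def random_keypoints(rng, image_size=(128, 128), margin=4.0):
    """Six random in-bounds keypoints (no geometric structure needed)."""
    H, W = image_size
    pts = np.column_stack(
        [
            rng.uniform(margin, H - 1 - margin, size=6),
            rng.uniform(margin, W - 1 - margin, size=6),
        ]
    )
    return KeypointSet(pts)
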