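import numpy as np
import pytest

from velogrid.camera import Camera, CameraIntrinsics, CameraPose, StereoRig, rectify


@pytest.fixture(scope="session")
def ideal_intrinsics():
    """A distortion-free camera with unit-scale pixels (f_px = 400)."""
    return CameraIntrinsics(
        f=4.0, kappa1=0.0, cx=100.0, cy=100.0, dx=0.01, dy=0.01,
        width=200, height=200,
    )


@pytest.fixture(scope="session")
def fronto_rig():
    """Fronto-parallel rig with baseline 4 mm along +x (already rectified)."""
    intr = CameraIntrinsics(
        f=4.0, kappa1=0.0, cx=100.0, cy=100.0, dx=0.01, dy=0.01,
        width=200, height=200,
    )
    left = Camera(intr, CameraPose(np.eye(3), np.zeros(3)))
    right = Camera(intr, CameraPose(np.eye(3), np.array([-4.0, 0.0, 0.0])))
    return rectify(StereoRig(left=left, right=right))
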