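import numpy as np
import pytest

from mocap3d import (Camera, CameraIntrinsics, CameraPose, CameraRig,
                     DistortionCoeffs, InitialLabeling, corrupt_detections)


@pytest.fixture
def pinhole_intrinsics():
    return CameraIntrinsics(fx=800.0, fy=800.0, cx=320.0, cy=240.0,
                            image_width=640, image_height=480)


@pytest.fixture
def ideal_camera(pinhole_intrinsics):
    """Identity-pose camera, zero distortion."""
    return Camera(pinhole_intrinsics)


@pytest.fixture
def distorted_camera(pinhole_intrinsics):
    """Same geometry with mild radial + tangential distortion."""
    return Camera(pinhole_intrinsics,
                  DistortionCoeffs(k1=0.1, k2=-0.02, p1=1e-3, p2=-5e-4,
                                   k3=0.005))


@pytest.fixture
def stereo_rig(pinhole_intrinsics):
    """Two parallel cameras at z=0 looking down +z, 200 mm baseline."""
    cam0 = Camera(pinhole_intrinsics)
    cam1 = Camera(pinhole_intrinsics,
                  pose=CameraPose(np.eye(3), np.array([-200.0, 0.0, 0.0])))
    return CameraRig([cam0, cam1], frame_rate_hz=750.0)


def labeling_from_index(index, t0, cameras):
    """Ground-truth initial labeling from a corrupt_detections index."""
    return InitialLabeling(
        t0=t0,
        assignments={c: dict(index[(t0, c)]) for c in cameras},
    )


@pytest.fixture
def noiseless_strike():
    """Seeded strike scene plus exact detections and truth labeling."""
    from mocap3d import strike_scene

    scene = strike_scene(duration_s=0.1, seed=11)
    ds, index = corrupt_detections(scene.truth_pixels, 0.0, 0.0, seed=11)
    lab = labeling_from_index(index, 0, range(len(scene.rig)))
    return scene, ds, lab
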