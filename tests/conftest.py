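import numpy as np
import pytest

from stimmap.imaging import EFieldVolume, VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(data, voxel_mm=1.0, origin=(0.0, 0.0, 0.0), units="unitless"):
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = origin
    return VoxelVolume(np.asarray(data, dtype=float), affine, units=units)


def make_efield(data, patient_id="p0", hemisphere="left", voxel_mm=1.0,
                origin=(0.0, 0.0, 0.0)):
    vol = make_volume(np.abs(data), voxel_mm=voxel_mm, origin=origin,
                      units="V_per_m")
    return EFieldVolume(vol, patient_id=patient_id, hemisphere=hemisphere)


@pytest.fixture
def volume_factory():
    return make_volume


@pytest.fixture
def efield_factory():
    return make_efield


def trilinear_oracle(volume: VoxelVolume, points_mm: np.ndarray) -> np.ndarray:
    """Independent per-point trilinear interpolation (zero outside)."""
    out = np.zeros(len(points_mm))
    inv = np.linalg.inv(volume.affine)
    shape = volume.data.shape
    for n, p in enumerate(np.atleast_2d(points_mm)):
        v = inv[:3, :3] @ p + inv[:3, 3]
        i0 = np.floor(v).astype(int)
        f = v - i0
        acc = 0.0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    idx = i0 + (di, dj, dk)
                    if np.any(idx < 0) or np.any(idx >= shape):
                        val = 0.0
                    else:
                        val = volume.data[tuple(idx)]
                    w = ((f[0] if di else 1 - f[0])
                         * (f[1] if dj else 1 - f[1])
                         * (f[2] if dk else 1 - f[2]))
                    acc += w * val
        out[n] = acc
    return out
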