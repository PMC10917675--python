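"""Volume/streamline I/O and geometric primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stimmap.imaging import (
    StreamlineFormatError,
    StreamlineSet,
    VolumeFormatError,
    VoxelVolume,
    gaussian_smooth,
    load_streamlines,
    load_volume,
    resample_polyline,
    resample_to_grid,
    sample_along_streamline,
    save_streamlines,
    save_volume,
    streamline_density_map,
    mirror_volume_x,
)

from conftest import make_volume, trilinear_oracle


# ---------------------------------------------------------------- volumes

def test_volume_roundtrip_bit_identical(tmp_path, rng):
    vol = make_volume(rng.random((7, 6, 5)).astype(np.float32), voxel_mm=0.7,
                      origin=(-3, 2, 1), units="V_per_m")
    save_volume(vol, tmp_path / "v.nii.gz")
    back = load_volume(tmp_path / "v.nii.gz")
    np.testing.assert_array_equal(back.data, vol.data)
    np.testing.assert_allclose(back.affine, vol.affine, atol=1e-6)
    assert back.units == "V_per_m"


def test_load_sanitizes_nan_with_warning(tmp_path, rng, caplog):
    data = rng.random((4, 4, 4))
    data[1, 2, 3] = np.nan
    import nibabel as nib
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "n.nii.gz"))
    with caplog.at_level("WARNING"):
        vol = load_volume(tmp_path / "n.nii.gz")
    assert vol.data[1, 2, 3] == 0.0
    assert np.all(np.isfinite(vol.data))
    assert any("non-finite" in r.message for r in caplog.records)


def test_load_rejects_4d(tmp_path, rng):
    import nibabel as nib
    nib.save(nib.Nifti1Image(rng.random((3, 3, 3, 2)), np.eye(4)),
             str(tmp_path / "v4.nii.gz"))
    with pytest.raises(VolumeFormatError, match="v4"):
        load_volume(tmp_path / "v4.nii.gz")


def test_affine_maps_voxel_centers():
    vol = make_volume(np.zeros((10, 10, 10)), voxel_mm=0.5)
    np.testing.assert_allclose(vol.voxel_to_world([2, 4, 6]), [1.0, 2.0, 3.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_world_voxel_roundtrip_random_affines(seed):
    """world -> voxel -> world is the identity within 1e-9."""
    rng = np.random.default_rng(seed)
    A = np.eye(4)
    A[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    A[:3, 3] = rng.normal(scale=20, size=3)
    vol = VoxelVolume(np.zeros((3, 3, 3)), A)
    pts = rng.normal(scale=30, size=(20, 3))
    back = np.atleast_2d(vol.voxel_to_world(vol.world_to_voxel(pts)))
    np.testing.assert_allclose(back, pts, atol=1e-9)


# ------------------------------------------------------------- sampling

def test_sampling_constant_volume(rng):
    vol = make_volume(np.full((8, 8, 8), 3.7))
    line = np.array([[1.0, 1.0, 1.0], [5.5, 4.0, 6.0]])
    vals = sample_along_streamline(vol, line, step_mm=0.5)
    np.testing.assert_allclose(vals, 3.7)


def test_sampling_outside_grid_is_zero():
    vol = make_volume(np.ones((5, 5, 5)))
    line = np.array([[100.0, 100, 100], [120.0, 100, 100]])
    assert np.all(sample_along_streamline(vol, line) == 0)


def test_sampling_linear_ramp_matches_analytic():
    shape = (20, 6, 6)
    ii = np.arange(shape[0], dtype=float)
    data = np.broadcast_to(ii[:, None, None], shape).copy()  # f(x) = x
    vol = make_volume(data)
    line = np.array([[2.2, 2.0, 2.0], [15.8, 2.0, 2.0]])
    dense = resample_polyline(line, 0.5)
    vals = sample_along_streamline(vol, line, step_mm=0.5)
    np.testing.assert_allclose(vals, dense[:, 0], atol=1e-6)


def test_sampling_matches_independent_trilinear_oracle(rng):
    for _ in range(25):
        vol = make_volume(rng.random((6, 7, 5)), voxel_mm=rng.uniform(0.5, 2.0),
                          origin=rng.normal(scale=3, size=3))
        line = rng.normal(scale=4, size=(4, 3)) + vol.voxel_to_world([3, 3, 2])
        dense = resample_polyline(line, 0.5)
        got = sample_along_streamline(vol, line, step_mm=0.5)
        np.testing.assert_allclose(got, trilinear_oracle(vol, dense), atol=1e-6)


def test_resample_retains_vertices_and_spacing():
    line = np.array([[0.0, 0, 0], [3.0, 0, 0], [3.0, 4.0, 0]])
    dense = resample_polyline(line, 0.7)
    for v in line:
        assert np.min(np.linalg.norm(dense - v, axis=1)) < 1e-12
    steps = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    assert np.all(steps <= 0.7 + 1e-12)


def test_degenerate_polyline_errors():
    vol = make_volume(np.ones((4, 4, 4)))
    with pytest.raises(ValueError):
        sample_along_streamline(vol, np.array([[1.0, 1, 1]]))


# ------------------------------------------------------------- density map

def test_density_line_along_axis():
    grid = make_volume(np.zeros((10, 5, 5)))
    sl = StreamlineSet([np.array([[0.0, 2, 2], [9.0, 2, 2]])])
    dm = streamline_density_map(sl, grid)
    assert dm.data.sum() == 10
    assert np.all(dm.data[:, 2, 2] == 1)


def test_density_empty_and_duplication(rng):
    grid = make_volume(np.zeros((8, 8, 8)))
    assert streamline_density_map(StreamlineSet([]), grid).data.sum() == 0
    sls = [rng.uniform(0, 7, size=(5, 3)) for _ in range(4)]
    once = streamline_density_map(StreamlineSet(sls), grid)
    twice = streamline_density_map(StreamlineSet(sls + sls), grid)
    np.testing.assert_array_equal(twice.data, 2 * once.data)


def test_density_matches_bruteforce_voxel_visits(rng):
    grid = make_volume(np.zeros((6, 6, 6)))
    sls = [rng.uniform(0.5, 5.0, size=(4, 3)) for _ in range(5)]
    dm = streamline_density_map(StreamlineSet(sls), grid, step_mm=0.25)
    brute = np.zeros(grid.shape)
    for sl in sls:
        dense = resample_polyline(sl, 0.25)
        vox = {tuple(np.round(v).astype(int)) for v in dense}
        for v in vox:
            if all(0 <= c < 6 for c in v):
                brute[v] += 1
    np.testing.assert_array_equal(dm.data, brute)


# ------------------------------------------------------------- smoothing

def test_smooth_identity_and_mass():
    delta = np.zeros((41, 41, 41))
    delta[20, 20, 20] = 1.0
    vol = make_volume(delta)
    same = gaussian_smooth(vol, 0.0)
    np.testing.assert_array_equal(same.data, vol.data)
    sm = gaussian_smooth(vol, 8.0)
    assert abs(sm.data.sum() - 1.0) < 1e-6


def test_smooth_delta_matches_analytic_gaussian_ratio():
    delta = np.zeros((41, 41, 41))
    delta[20, 20, 20] = 1.0
    sm = gaussian_smooth(make_volume(delta), 8.0)
    sigma = 8.0 / (2 * math.sqrt(2 * math.log(2)))
    expected = math.exp(1.0 / (2 * sigma**2))
    got = sm.data[20, 20, 20] / sm.data[21, 20, 20]
    assert got == pytest.approx(expected, rel=1e-3)


def test_smooth_negative_fwhm_errors():
    with pytest.raises(ValueError):
        gaussian_smooth(make_volume(np.zeros((3, 3, 3))), -1.0)


def test_mirror_volume_flips_world_x():
    data = np.zeros((9, 5, 5))
    data[1, 2, 2] = 5.0
    vol = make_volume(data, origin=(-4, 0, 0))  # grid symmetric about x=0
    mirrored = mirror_volume_x(vol)
    assert mirrored.data[7, 2, 2] == pytest.approx(5.0)
    assert mirrored.data[1, 2, 2] == pytest.approx(0.0)


def test_resample_to_grid_identity_and_shift():
    vol = make_volume(np.arange(27, dtype=float).reshape(3, 3, 3))
    same = resample_to_grid(vol, vol)
    np.testing.assert_array_equal(same.data, vol.data)


# ------------------------------------------------------------- streamlines

def _parse_tck(path):
    """Minimal independent TCK parser (text header, float32 triplets)."""
    raw = open(path, "rb").read()
    header, _, rest = raw.partition(b"END\n")
    offset = int([l for l in header.split(b"\n") if l.startswith(b"file:")][0].split()[-1])
    pts = np.frombuffer(raw[offset:], dtype="<f4").reshape(-1, 3)
    streamlines, current = [], []
    for p in pts:
        if np.all(np.isnan(p)):
            if current:
                streamlines.append(np.array(current))
                current = []
        elif np.all(np.isinf(p)):
            break
        else:
            current.append(p)
    return streamlines


@pytest.mark.parametrize("ext", ["trk", "tck"])
def test_streamline_roundtrip(tmp_path, rng, ext):
    sls = [rng.normal(scale=10, size=(n, 3)) for n in (2, 5, 9)]
    sset = StreamlineSet(sls)
    path = tmp_path / f"s.{ext}"
    save_streamlines(sset, path)
    back = load_streamlines(path)
    assert len(back) == 3
    for a, b in zip(sls, back):
        assert len(a) == len(b)
        np.testing.assert_allclose(a, b, atol=1e-3)


def test_streamline_empty_set_roundtrip(tmp_path):
    path = tmp_path / "empty.tck"
    save_streamlines(StreamlineSet([]), path)
    assert len(load_streamlines(path)) == 0


def test_trk_tck_trk_conversion_and_independent_parse(tmp_path):
    """A known 2-point line survives TRK -> TCK -> TRK, and the TCK stage
    agrees with a hand-written header parse."""
    line = np.array([[1.0, -2.0, 3.0], [4.0, 5.0, -6.0]])
    p1, p2, p3 = tmp_path / "a.trk", tmp_path / "b.tck", tmp_path / "c.trk"
    save_streamlines(StreamlineSet([line]), p1)
    save_streamlines(load_streamlines(p1), p2)
    save_streamlines(load_streamlines(p2), p3)
    np.testing.assert_allclose(load_streamlines(p3)[0], line, atol=1e-3)
    oracle = _parse_tck(p2)
    assert len(oracle) == 1
    np.testing.assert_allclose(oracle[0], line, atol=1e-3)


def test_unknown_streamline_format_errors(tmp_path):
    with pytest.raises(StreamlineFormatError):
        load_streamlines(tmp_path / "x.vtk")
    with pytest.raises(StreamlineFormatError):
        save_streamlines(StreamlineSet([]), tmp_path / "x.vtk")


def test_streamline_set_validation():
    with pytest.raises(ValueError):
        StreamlineSet([np.array([[0.0, 0, 0]])])  # < 2 points
    with pytest.raises(ValueError):
        StreamlineSet([np.array([[0.0, 0, 0], [np.nan, 0, 0]])])
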