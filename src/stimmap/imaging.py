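"""Volume and streamline containers, I/O, and geometric primitives.

Coordinate contract
-------------------
All world coordinates are millimetres.  Continuous voxel indices are
0-based and a voxel's *center* maps through the affine (the NIfTI
convention), so world -> voxel -> world round-trips exactly.  Volume
values are interpolated trilinearly; points outside the grid contribute
zero, which is the right behaviour for compactly supported stimulation
fields.

Volumes are NIfTI-1 on disk (float32); statistics are computed in
double precision in memory.  Streamlines are TRK or TCK on disk and are
always handed around in world mm regardless of the on-disk convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from nibabel.streamlines import TckFile, Tractogram, TrkFile
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "EFieldVolume",
    "StreamlineSet",
    "load_volume",
    "save_volume",
    "load_streamlines",
    "save_streamlines",
    "resample_polyline",
    "sample_along_streamline",
    "streamline_density_map",
    "gaussian_smooth",
    "resample_to_grid",
    "mirror_volume_x",
]

logger = logging.getLogger(__name__)

#: Valid unit tags for :class:`VoxelVolume`.
UNITS = ("V_per_m", "correlation", "count", "unitless")

# Default arclength step for sampling fields along streamlines, in mm.
# Below typical voxel size so field peaks are not missed.
DEFAULT_STEP_MM = 0.5

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class VolumeFormatError(ValueError):
    """Raised for unreadable or non-3D volume files."""


class StreamlineFormatError(ValueError):
    """Raised for streamline files whose spatial convention is unclear."""


@dataclass
class VoxelVolume:
    """A 3D scalar grid with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (i, j, k)
        Scalar values; finite everywhere (background is 0, never NaN).
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm transform (voxel centers).
    units : str
        One of ``V_per_m``, ``correlation``, ``count``, ``unitless``.
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = "unitless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T + self.affine[:3, 3]).squeeze()

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (xyz @ inv[:3, :3].T + inv[:3, 3]).squeeze()

    def sample_world(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world-mm points; outside -> 0."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        vox = np.atleast_2d(self.world_to_voxel(pts))
        # grid-constant: values beyond the edge are zero-padded, so the
        # interpolation fades linearly to 0 at the boundary
        return ndimage.map_coordinates(
            self.data, vox.T, order=1, mode="grid-constant", cval=0.0
        )

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.affine.copy(), self.units)

    def like(self, data: np.ndarray, units: str | None = None) -> "VoxelVolume":
        """New volume on this grid with different data."""
        return VoxelVolume(data, self.affine.copy(), units or self.units)

    def same_grid(self, other: "VoxelVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class EFieldVolume:
    """One hemisphere's stimulation field (E-field magnitude, V/m)."""

    volume: VoxelVolume
    patient_id: str
    hemisphere: str  # "left" | "right"
    active_contact_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.volume.units != "V_per_m":
            raise ValueError("E-field volumes must carry V_per_m units")
        if np.any(self.volume.data < 0):
            raise ValueError("E-field magnitudes must be non-negative")
        self.active_contact_mm = np.asarray(self.active_contact_mm, dtype=float)


@dataclass
class StreamlineSet:
    """Ordered collection of polylines in world-mm template space."""

    streamlines: list[np.ndarray]
    space_tag: str = "template-mm"

    def __post_init__(self) -> None:
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (n>=2, 3) point array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return StreamlineSet([self.streamlines[i] for i in idx], self.space_tag)
        return self.streamlines[idx]


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | Path) -> VoxelVolume:
    """Load a single-volume 3D NIfTI file.

    NaNs are replaced by 0 with a logged warning; 4D or unreadable input
    raises :class:`VolumeFormatError` naming the path.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    n_bad = int(np.sum(~np.isfinite(data)))
    if n_bad:
        logger.warning("%s: replaced %d non-finite voxels with 0", path, n_bad)
        data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    units = "unitless"
    descrip = str(np.asarray(img.header.get("descrip", b"")).tobytes().decode("ascii", "ignore")).strip("\x00")
    for tag in UNITS:
        if f"units={tag}" in descrip:
            units = tag
            break
    return VoxelVolume(data, np.asarray(img.affine, dtype=float), units)


def save_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a NIfTI-1 file (float32 on disk); units in the descrip field."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header["descrip"] = f"units={volume.units}".encode("ascii")
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write volume {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Streamline I/O
# ---------------------------------------------------------------------------

def load_streamlines(path: str | Path) -> StreamlineSet:
    """Load a TRK or TCK file; points are returned in world mm (RAS).

    nibabel applies each format's on-disk voxel convention, so the
    returned coordinates are comparable across formats.  Unknown
    extensions raise rather than guess.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".trk", ".tck"):
        raise StreamlineFormatError(f"{path}: unknown streamline format {suffix!r}")
    tractogram = nib.streamlines.load(str(path)).tractogram
    sls = [np.asarray(s, dtype=float) for s in tractogram.streamlines]
    return StreamlineSet(sls)


def save_streamlines(sset: StreamlineSet, path: str | Path,
                     reference: VoxelVolume | None = None) -> None:
    """Write TRK or TCK.  Points are already world mm (rasmm).

    TRK headers need a voxel grid; ``reference`` supplies it, otherwise a
    1 mm identity grid bounding the streamlines is synthesised.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    tractogram = Tractogram(list(sset.streamlines), affine_to_rasmm=np.eye(4))
    if suffix == ".tck":
        TckFile(tractogram).save(str(path))
    elif suffix == ".trk":
        if reference is not None:
            affine, dims = reference.affine, reference.shape
        else:
            affine, dims = _bounding_grid(sset.streamlines)
        header = {
            "voxel_to_rasmm": affine.astype(np.float32),
            "voxel_sizes": np.linalg.norm(affine[:3, :3], axis=0).astype(np.float32),
            "dimensions": np.asarray(dims, dtype=np.int16),
            "voxel_order": "".join(nib.aff2axcodes(affine)),
        }
        TrkFile(tractogram, header=header).save(str(path))
    else:
        raise StreamlineFormatError(f"{path}: unknown streamline format {suffix!r}")


def _bounding_grid(streamlines: Sequence[np.ndarray]) -> tuple[np.ndarray, tuple[int, int, int]]:
    if streamlines:
        pts = np.vstack(streamlines)
        lo = np.floor(pts.min(axis=0)) - 2
        hi = np.ceil(pts.max(axis=0)) + 2
    else:
        lo, hi = np.zeros(3), np.ones(3) * 10
    affine = np.eye(4)
    affine[:3, 3] = lo
    dims = tuple(int(d) for d in (hi - lo + 1))
    return affine, dims


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def resample_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample at arclength spacing <= ``step_mm``, retaining the
    original vertices (each segment is subdivided evenly)."""
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(math.ceil(seg / step_mm)))
        for t in np.linspace(0.0, 1.0, n + 1)[1:]:
            out.append(a + t * (b - a))
    return np.asarray(out)


def sample_along_streamline(volume: VoxelVolume, polyline: np.ndarray,
                            step_mm: float = DEFAULT_STEP_MM) -> np.ndarray:
    """Trilinear samples of ``volume`` along the resampled polyline.

    Out-of-grid points contribute 0.  The peak of the returned vector is
    the streamline's "stimulation impact" under that field.
    """
    dense = resample_polyline(polyline, step_mm)
    return volume.sample_world(dense)


def streamline_density_map(sset: StreamlineSet, grid: VoxelVolume,
                           step_mm: float | None = None) -> VoxelVolume:
    """Voxelised streamline visitation counts.

    Each voxel counts the number of streamlines with at least one sampled
    point inside it; a streamline counts at most once per voxel.
    """
    counts = np.zeros(grid.shape, dtype=float)
    if step_mm is None:
        step_mm = float(grid.spacing.min()) / 2.0
    inv = np.linalg.inv(grid.affine)
    for sl in sset:
        dense = resample_polyline(sl, step_mm)
        vox = dense @ inv[:3, :3].T + inv[:3, 3]
        idx = np.round(vox).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        if not np.any(ok):
            continue
        uniq = np.unique(idx[ok], axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return grid.like(counts, units="count")


def gaussian_smooth(volume: VoxelVolume, fwhm_mm: float) -> VoxelVolume:
    """Gaussian smoothing with a kernel stated as FWHM in mm.

    Sigma is set per axis from the voxel size so anisotropic grids are
    honoured; ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / volume.spacing
    smoothed = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="constant")
    return volume.like(smoothed)


def resample_to_grid(volume: VoxelVolume, grid: VoxelVolume) -> VoxelVolume:
    """Resample ``volume`` onto ``grid`` (trilinear, outside -> 0)."""
    if volume.same_grid(grid):
        return volume.copy()
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    vals = volume.sample_world(world)
    return grid.like(vals.reshape(grid.shape), units=volume.units)


def mirror_volume_x(volume: VoxelVolume) -> VoxelVolume:
    """Mirror a volume across the template midline (world x = 0).

    Implemented by resampling the flipped field F'(x,y,z) = F(-x,y,z)
    onto the same grid, so it works for any affine.
    """
    flip = np.diag([-1.0, 1.0, 1.0])
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in volume.shape], indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = ijk @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    vals = volume.sample_world(world @ flip.T)
    return volume.like(vals.reshape(volume.shape))
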