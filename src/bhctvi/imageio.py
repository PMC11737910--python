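"""Volume and displacement-field containers plus NIfTI-1 round-trip I/O.

Every module in the package exchanges image geometry exclusively through
:class:`ImageVolume` / :class:`DisplacementField`: a 3D scalar (or 4D
vector) array on a regular grid with per-axis voxel spacing in mm and a
grid origin at the centre of voxel (0, 0, 0).

Patient-axis convention (fixed package-wide): axis 0 = x, patient
right → left; axis 1 = y, anterior → posterior; axis 2 = z,
inferior → superior.  Voxel centre of index (i, j, k) sits at
``origin_mm + index * spacing_mm``.  On disk the grid is stored as
NIfTI-1 with a diagonal affine carrying exactly this convention, so a
write → read round trip is bit-exact for the payload and exact to
float precision for the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "DisplacementField",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_dvf",
    "write_dvf",
]


class GeometryError(ValueError):
    """Raised when an on-disk file or an argument violates the grid contract."""


def _as_vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).reshape(-1)
    if arr.size != 3:
        raise GeometryError(f"{name} must have 3 components, got {arr.size}")
    return arr


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid (HU for CT, dimensionless for derived maps)."""

    data: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise GeometryError(f"volume data must be 3D, got ndim={data.ndim}")
        spacing = _as_vec3(self.spacing_mm, "spacing_mm")
        origin = _as_vec3(self.origin_mm, "origin_mm")
        if np.any(spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates in mm (broadcastable 1D arrays)."""
        return tuple(  # type: ignore[return-value]
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def same_grid(self, other: "ImageVolume | DisplacementField", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel displacement u(x, y, z) in mm on a fixed grid.

    ``vectors`` has shape ``grid_shape + (3,)``; component order matches
    the patient axes.  The field maps a fixed-grid (expiration) point to
    its corresponding moving-image (inspiration) position ``x + u(x)``.
    """

    vectors: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        vec = np.asarray(self.vectors)
        if vec.ndim != 4 or vec.shape[-1] != 3:
            raise GeometryError(
                f"displacement field must have shape (nx, ny, nz, 3), got {vec.shape}"
            )
        spacing = _as_vec3(self.spacing_mm, "spacing_mm")
        origin = _as_vec3(self.origin_mm, "origin_mm")
        if np.any(spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        return ImageVolume.same_grid(self, other, tol)  # type: ignore[arg-type]

    def coords_mm(self):
        return ImageVolume.coords_mm(self)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _check_affine(aff: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    lin = aff[:3, :3]
    if np.any(np.abs(lin - np.diag(np.diag(lin))) > 1e-6):
        raise GeometryError(
            f"{path}: affine (sform/qform) has off-diagonal terms; only "
            "axis-aligned grids in the package patient-axis convention are supported"
        )
    spacing = np.diag(lin).copy()
    if np.any(spacing <= 0):
        raise GeometryError(f"{path}: affine implies non-positive voxel spacing {spacing}")
    return spacing, aff[:3, 3].copy()


def write_volume(volume: ImageVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data), _affine(volume.spacing_mm, volume.origin_mm))
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    return path


def read_volume(path) -> ImageVolume:
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, file dim={data.ndim}")
    spacing, origin = _check_affine(img.affine, path)
    return ImageVolume(data=data, spacing_mm=spacing, origin_mm=origin)


def write_dvf(dvf: DisplacementField, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(dvf.vectors), _affine(dvf.spacing_mm, dvf.origin_mm))
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    return path


def read_dvf(path) -> DisplacementField:
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise GeometryError(f"{path}: expected a 4D displacement field, file dim={data.ndim}")
    if data.shape[-1] != 3:
        raise GeometryError(
            f"{path}: displacement component axis must have length 3, got {data.shape[-1]}"
        )
    spacing, origin = _check_affine(img.affine, path)
    return DisplacementField(vectors=data, spacing_mm=spacing, origin_mm=origin)


def require_same_grid(a, b, what: str = "inputs") -> None:
    """Raise GeometryError unless a and b share shape, spacing and origin."""
    if not (
        a.shape == b.shape
        and np.allclose(a.spacing_mm, b.spacing_mm, atol=1e-6)
        and np.allclose(a.origin_mm, b.origin_mm, atol=1e-6)
    ):
        raise GeometryError(
            f"geometry mismatch between {what}: "
            f"shape {a.shape} vs {b.shape}, spacing {a.spacing_mm} vs {b.spacing_mm}, "
            f"origin {a.origin_mm} vs {b.origin_mm}"
        )
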