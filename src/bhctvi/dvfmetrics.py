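"""Regional displacement-vector summaries and gravity-orientation statistics.

Two scalar statistics turn the qualitative reading of positional DVF
images into numbers:

* ``gravity_alignment`` — magnitude-weighted mean cosine between the
  per-voxel displacement and the gravity unit vector,
  Σ (u·ĝ) / Σ |u| over in-region voxels.  +1: motion along gravity,
  −1: motion opposite gravity (the supine dorsal→ventral signature),
  0: motion parallel to the ground.
* ``ground_parallelism`` — mean over voxels of the magnitude of the
  component of the unit displacement orthogonal to gravity,
  mean √(1 − (û·ĝ)²) ∈ [0, 1]; ≈1 is the prone signature (cranio-caudal
  motion parallel to the ground).

Voxels with |u| below a floor (default 0.5 mm) carry no orientation
information and are excluded; if no voxel passes the floor both statistics
are undefined (NaN) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageio import DisplacementField, ImageVolume

__all__ = ["VectorSummary", "region_vector_summary", "export_arrows"]

DEFAULT_MAGNITUDE_FLOOR_MM = 0.5


@dataclass(frozen=True)
class VectorSummary:
    n_voxels: int
    n_above_floor: int
    mean_vector_mm: np.ndarray
    mean_magnitude_mm: float
    gravity_alignment: float   # NaN when undefined
    ground_parallelism: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return self.n_above_floor > 0


def region_vector_summary(
    dvf: DisplacementField,
    region: np.ndarray | ImageVolume,
    gravity_unit_vector,
    magnitude_floor_mm: float = DEFAULT_MAGNITUDE_FLOOR_MM,
) -> VectorSummary:
    """Summarise displacement vectors over a region mask."""
    if isinstance(region, ImageVolume):
        region = np.asarray(region.data)
    m = np.asarray(region) != 0
    if m.shape != dvf.shape:
        raise ValueError(f"region shape {m.shape} does not match grid {dvf.shape}")
    if not m.any():
        raise ValueError("empty region")
    g = np.asarray(gravity_unit_vector, dtype=float).reshape(3)
    gn = np.linalg.norm(g)
    if gn == 0:
        raise ValueError("gravity vector must be nonzero")
    g = g / gn

    u = dvf.vectors[m]
    mag = np.sqrt((u**2).sum(axis=-1))
    mean_vec = u.mean(axis=0)
    mean_mag = float(mag.mean())

    sel = mag > magnitude_floor_mm
    if sel.any():
        us, ms = u[sel], mag[sel]
        alignment = float((us @ g).sum() / ms.sum())
        cos = (us @ g) / ms
        parallelism = float(np.sqrt(np.clip(1.0 - cos**2, 0.0, 1.0)).mean())
    else:
        alignment = parallelism = float("nan")

    return VectorSummary(
        n_voxels=int(m.sum()),
        n_above_floor=int(sel.sum()),
        mean_vector_mm=mean_vec,
        mean_magnitude_mm=mean_mag,
        gravity_alignment=alignment,
        ground_parallelism=parallelism,
    )


def export_arrows(
    dvf: DisplacementField,
    mask: np.ndarray | ImageVolume,
    stride: int = 4,
) -> pd.DataFrame:
    """Subsample in-mask vectors on a stride grid for quiver rendering.

    Rows are ordered lexicographically by voxel index; columns are the
    arrow foot position (mm), the vector components (mm) and the magnitude.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if isinstance(mask, ImageVolume):
        mask = np.asarray(mask.data)
    m = np.asarray(mask) != 0
    if m.shape != dvf.shape:
        raise ValueError(f"mask shape {m.shape} does not match grid {dvf.shape}")
    grid = np.zeros_like(m)
    grid[::stride, ::stride, ::stride] = True
    idx = np.argwhere(m & grid)
    pos = dvf.origin_mm + idx * dvf.spacing_mm
    u = dvf.vectors[tuple(idx.T)]
    mag = np.sqrt((u**2).sum(axis=-1))
    return pd.DataFrame(
        dict(
            x_mm=pos[:, 0], y_mm=pos[:, 1], z_mm=pos[:, 2],
            ux_mm=u[:, 0], uy_mm=u[:, 1], uz_mm=u[:, 2],
            magnitude_mm=mag,
        )
    )
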