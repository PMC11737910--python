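"""Lung segmentation, volumetry, cranio-caudal sections and ratio reports.

Segmentation is threshold-plus-morphology: air-like voxels (HU < −400)
that do not touch the grid border form candidate components; the two
largest are kept and assigned left/right by their centroid along the
patient x axis (a single fused component is split at the mid-sagittal
plane).

The four analysis sections (apical, middle, basal, diaphragm) are axial
slabs placed at fractional cranio-caudal positions within the lung
extent — a landmark-free surrogate for the aortic-arch / carina / heart /
diaphragm levels used when reading real CT.  Per lung and section the
report gives the percentage of voxels classified highly functional and
the section-lung volume in mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imageio import ImageVolume, require_same_grid

__all__ = [
    "SegmentationError",
    "SectionSet",
    "SECTION_NAMES",
    "DEFAULT_SECTION_FRACTIONS",
    "segment_lungs",
    "lung_volume",
    "define_sections",
    "functional_ratio",
]

SECTION_NAMES = ("apical", "middle", "basal", "diaphragm")
DEFAULT_SECTION_FRACTIONS = (0.15, 0.40, 0.65, 0.88)

LUNG_HU_THRESHOLD = -400.0


class SegmentationError(RuntimeError):
    pass


def segment_lungs(ct: ImageVolume) -> ImageVolume:
    """Label lungs in an HU-calibrated CT: 0 background, 1 left, 2 right.

    Raises :class:`SegmentationError` when no air-like component remains
    after discarding ambient air (components touching the grid border).
    """
    air = np.asarray(ct.data) < LUNG_HU_THRESHOLD
    labels, n = ndimage.label(air)
    if n == 0:
        raise SegmentationError("no air-like voxels below the HU threshold")

    border = np.zeros_like(air)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    ambient = np.unique(labels[border & air])
    keep = np.setdiff1d(np.arange(1, n + 1), ambient)
    if keep.size == 0:
        raise SegmentationError(
            "all air components touch the grid border (no body enclosing lungs)"
        )

    sizes = ndimage.sum_labels(air, labels, keep)
    order = keep[np.argsort(sizes)[::-1]]
    # drop tiny specks (noise voxels): keep components >= 1% of the largest
    largest = sizes.max()
    cands = [lab for lab in order[:2] if ndimage.sum_labels(air, labels, lab) >= 0.01 * largest]

    out = np.zeros(ct.shape, dtype=np.uint8)
    x_coords = ct.origin_mm[0] + ct.spacing_mm[0] * np.arange(ct.shape[0])
    x_mid = x_coords.mean()

    if len(cands) == 1:
        comp = labels == cands[0]
        cx = x_coords[np.nonzero(comp)[0]]
        span = cx.max() - cx.min()
        if span > 0.6 * (x_coords[-1] - x_coords[0]):
            # one fused component straddling the midline: split mid-sagittally
            xg = x_coords[:, None, None] * np.ones(ct.shape)
            out[comp & (xg > x_mid)] = 1
            out[comp & (xg <= x_mid)] = 2
        else:
            out[comp] = 1 if cx.mean() > x_mid else 2
    else:
        c0 = x_coords[np.nonzero(labels == cands[0])[0]].mean()
        c1 = x_coords[np.nonzero(labels == cands[1])[0]].mean()
        left_lab, right_lab = (cands[0], cands[1]) if c0 > c1 else (cands[1], cands[0])
        out[labels == left_lab] = 1
        out[labels == right_lab] = 2

    return ct.with_data(out)


def lung_volume(mask: ImageVolume, lung: str = "total") -> float:
    """Volume in mL of the selected lung ('left', 'right' or 'total')."""
    lab = np.asarray(mask.data)
    if lung == "left":
        n = int((lab == 1).sum())
    elif lung == "right":
        n = int((lab == 2).sum())
    elif lung == "total":
        n = int((lab > 0).sum())
    else:
        raise ValueError(f"unknown lung selector {lung!r}")
    return n * mask.voxel_volume_mm3 / 1000.0


@dataclass(frozen=True)
class SectionSet:
    """Axial slab ROIs, ordered cranial→caudal, as inclusive z-index ranges."""

    names: tuple[str, ...]
    z_ranges: tuple[tuple[int, int], ...]  # inclusive (lo, hi) array indices

    def __post_init__(self):
        prev_hi = None
        for name, (lo, hi) in zip(self.names, self.z_ranges):
            if lo > hi:
                raise ValueError(f"section {name}: empty slab {lo}..{hi}")
            # z index decreases cranial→caudal (z axis points superior)
            if prev_hi is not None and hi >= prev_hi:
                raise ValueError(f"sections overlap or are out of order at {name}")
            prev_hi = lo
        object.__setattr__(self, "z_ranges", tuple((int(a), int(b)) for a, b in self.z_ranges))

    def slab_mask(self, name: str, shape) -> np.ndarray:
        lo, hi = dict(zip(self.names, self.z_ranges))[name]
        m = np.zeros(shape, dtype=bool)
        m[:, :, lo : hi + 1] = True
        return m


def define_sections(
    mask: ImageVolume,
    fractions: tuple[float, ...] = DEFAULT_SECTION_FRACTIONS,
    slab_thickness: int = 3,
    names: tuple[str, ...] = SECTION_NAMES,
) -> SectionSet:
    """Place axial slabs at fractional cranio-caudal positions in the lungs.

    Fraction f positions a slab centre at apex + f × (base − apex) counted
    in slices from the lung apex (f = 0 apex, f = 1 base); each slab spans
    ``slab_thickness`` slices, clipped to the lung extent.  Overlapping
    slabs are rejected.
    """
    if len(fractions) != len(names):
        raise ValueError("need one fraction per section name")
    if slab_thickness < 1:
        raise ValueError("slab_thickness must be >= 1")
    lab = np.asarray(mask.data)
    zs = np.nonzero(lab.any(axis=(0, 1)))[0]
    if zs.size == 0:
        raise ValueError("empty lung mask")
    apex, base = int(zs.max()), int(zs.min())  # z axis points superior
    half_lo = (slab_thickness - 1) // 2
    half_hi = slab_thickness - 1 - half_lo
    ranges = []
    for f in fractions:
        center = apex - int(round(f * (apex - base)))
        lo = max(base, center - half_hi)
        hi = min(apex, center + half_lo)
        ranges.append((lo, hi))
    return SectionSet(names=tuple(names), z_ranges=tuple(ranges))


def functional_ratio(
    hf_mask: np.ndarray | ImageVolume,
    lungs: ImageVolume,
    sections: SectionSet,
) -> pd.DataFrame:
    """Tabulate the highly-functional fraction per lung and section.

    Returns a DataFrame with columns ``lung, section, n_voxels, ratio_pct,
    volume_ml``; an empty section∩lung yields NaN ratio (flagged, not 0).
    """
    if isinstance(hf_mask, ImageVolume):
        require_same_grid(hf_mask, lungs, "functional mask and lung mask")
        hf = np.asarray(hf_mask.data) != 0
    else:
        hf = np.asarray(hf_mask) != 0
    if hf.shape != lungs.shape:
        raise ValueError(f"mask shape {hf.shape} does not match lungs {lungs.shape}")
    lab = np.asarray(lungs.data)
    vox_ml = lungs.voxel_volume_mm3 / 1000.0
    rows = []
    for lung_name, code in (("left", 1), ("right", 2)):
        lung_sel = lab == code
        for name in sections.names:
            sel = lung_sel & sections.slab_mask(name, lab.shape)
            n = int(sel.sum())
            ratio = 100.0 * hf[sel].sum() / n if n else np.nan
            rows.append(
                dict(lung=lung_name, section=name, n_voxels=n,
                     ratio_pct=ratio, volume_ml=n * vox_ml)
            )
    return pd.DataFrame(rows)
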