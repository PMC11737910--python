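"""Synthetic breathing-thorax phantom with analytically known deformation.

Generates paired expiration/inspiration CT volumes (HU) for the four body
positions (supine, prone, right/left lateral decubitus) together with the
exact expiration→inspiration displacement field, so the whole ventilation
pipeline can be validated without volunteer scans.

Patient axes: x right→left, y anterior→posterior, z inferior→superior.
Gravity unit vectors: supine +y, prone −y, right lateral −x, left lateral +x
(the dependent lung side is the side the gravity vector points toward).

The ground-truth deformation is built from single-coordinate building
blocks arranged in a triangular dependency pattern — u_x(x, y), u_y(y),
u_z(x, y, z) — so that det(I + ∇u) reduces exactly to the product of the
three diagonal strains wherever the boundary envelope is inactive.  Inside
the lungs the Jacobian therefore has the closed form

    J(x) = (1 + k)^2 (1 + k_z) * m(s),    m(s) = 1 + γ (s − s0),

where k / k_z are transverse / cranio-caudal base strains, s the
coordinate along gravity and m a linear "gravity modulation" making the
dependent side expand more.  The base strain k is calibrated so that the
mean lung Jacobian equals ``global_expansion`` (the tidal volume ratio,
default 1.30).

Position-specific motion mechanisms (same Jacobian form, different
displacement directions, following the observed positional physiology):

* supine / laterals — the gravity modulation is carried by a displacement
  component along −gravity (in supine: dorsal→ventral motion, i.e. the
  chest wall is pushed away from the dependent side);
* prone — gravity-decoupled, diaphragm-dominant motion: the modulation is
  split between cranio-caudal (z) and lateral (x) stretches, both parallel
  to the ground, with essentially no displacement along gravity.

Inspiration intensities follow gas-dilution physics: parenchymal density
is rescaled as HU' = −1000 + (HU + 1000)/J, so expansion both moves and
darkens lung tissue.  Lungs carry smooth random texture (vasculature
surrogate) that deforms consistently between the phases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .imageio import DisplacementField, ImageVolume, write_dvf, write_volume
from .ventilation import jacobian_map

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "LungGeometry",
    "TissueHU",
    "AnalyticDVF",
    "FoldingError",
    "GRAVITY_VECTORS",
    "POSITIONS",
    "analytic_dvf",
    "generate_phantom",
]

POSITIONS = ("supine", "prone", "right_lateral", "left_lateral")

GRAVITY_VECTORS: dict[str, np.ndarray] = {
    "supine": np.array([0.0, 1.0, 0.0]),
    "prone": np.array([0.0, -1.0, 0.0]),
    "right_lateral": np.array([-1.0, 0.0, 0.0]),
    "left_lateral": np.array([1.0, 0.0, 0.0]),
}

# cranio-caudal / transverse strain anisotropy (diaphragm breathing dominates)
ANISOTROPY = 2.0
# elliptical body radius at which the boundary envelope starts decaying
ENVELOPE_INNER = 0.82
# prone: fraction of the gravity modulation carried by the lateral stretch
# (the remainder goes to the cranio-caudal stretch)
PRONE_X_SHARE = 0.25
# share of the gravity gradient repeated as a cranio-caudal (diaphragm-ward)
# expansion gradient within the lungs
CAUDAL_SHARE = 0.25
# decay scales of the smooth confinement tapers (in lung-ellipse units)
FOOT_DECAY = 0.5
QFOOT_DECAY = 0.45
# width of the rendered tissue interfaces (partial-volume / scanner PSF)
PV_WIDTH_MM = 4.0
# how far the smooth analytic deformation segments extend beyond the lung
# band before any clip or ramp (keeps derivative kinks off the lung surface)
KINK_MARGIN_MM = 0.0
# default geometry as fractions of the physical grid extent per axis
BODY_SEMI_FRAC = (0.448, 0.375, 0.469)
LUNG_SEMI_FRAC = (0.115, 0.156, 0.208)
LUNG_OFFSET_FRAC = 0.146


class FoldingError(ValueError):
    """The requested deformation folds (Jacobian ≤ 0 somewhere in the body)."""


@dataclass(frozen=True)
class TissueHU:
    lung: float = -780.0
    soft: float = 40.0
    spine: float = 700.0
    air: float = -1000.0


@dataclass(frozen=True)
class LungGeometry:
    """Two lung ellipsoids (shared semi-axes, mirrored centres) in mm."""

    semi_axes_mm: tuple[float, float, float]
    left_center_mm: tuple[float, float, float]
    right_center_mm: tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_geometry: LungGeometry | None = None
    tissue_hu: TissueHU = field(default_factory=TissueHU)
    position: str = "supine"
    global_expansion: float = 1.30
    gravity_gradient: float = 0.30
    noise_sd_hu: float = 20.0
    texture_sd_hu: float = 40.0
    texture_corr_mm: float = 8.0
    density_rescale: bool = True
    lungs: str = "both"  # "both" | "left" | "right"
    seed: int = 0

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}, expected one of {POSITIONS}")
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive sizes (>=8), got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.global_expansion <= 0:
            raise ValueError("global_expansion must be > 0")
        if self.lungs not in ("both", "left", "right"):
            raise ValueError(f"lungs must be 'both', 'left' or 'right', got {self.lungs!r}")
        if self.noise_sd_hu < 0 or self.texture_sd_hu < 0:
            raise ValueError("noise/texture SD must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=lambda o: list(o))

    @staticmethod
    def from_json(text: str) -> "PhantomSpec":
        d = json.loads(text)
        if d.get("lung_geometry") is not None:
            lg = d["lung_geometry"]
            d["lung_geometry"] = LungGeometry(
                semi_axes_mm=tuple(lg["semi_axes_mm"]),
                left_center_mm=tuple(lg["left_center_mm"]),
                right_center_mm=tuple(lg["right_center_mm"]),
            )
        if d.get("tissue_hu") is not None:
            d["tissue_hu"] = TissueHU(**d["tissue_hu"])
        d["grid_shape"] = tuple(d["grid_shape"])
        d["spacing_mm"] = tuple(d["spacing_mm"])
        return PhantomSpec(**d)


@dataclass
class PhantomPair:
    """Exhale/inhale volumes plus the generating ground truth."""

    exhale: ImageVolume
    inhale: ImageVolume
    truth_dvf: DisplacementField
    truth_lungs: ImageVolume          # labels on the exhale grid: 1 left, 2 right
    truth_lungs_inhale: ImageVolume   # same labels, inspiration phase
    gravity_unit_vector: np.ndarray
    spec: PhantomSpec
    meta: dict

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_volume(self.exhale, directory / "exhale.nii.gz")
        write_volume(self.inhale, directory / "inhale.nii.gz")
        write_dvf(self.truth_dvf, directory / "truth_dvf.nii.gz")
        write_volume(
            self.truth_lungs.with_data(self.truth_lungs.data.astype(np.uint8)),
            directory / "truth_lungs.nii.gz",
        )
        write_volume(
            self.truth_lungs_inhale.with_data(self.truth_lungs_inhale.data.astype(np.uint8)),
            directory / "truth_lungs_inhale.nii.gz",
        )
        (directory / "phantom_spec.json").write_text(self.spec.to_json())
        return directory


# ---------------------------------------------------------------------------
# analytic oracle fields


@dataclass(frozen=True)
class AnalyticDVF:
    """A displacement field with (where available) a closed-form Jacobian."""

    field: DisplacementField
    closed_form_jacobian: object | None  # callable (N,3) mm -> (N,) or None


def _grid_points(shape, spacing, origin):
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return pts


def analytic_dvf(kind: str, params: dict, grid: ImageVolume | DisplacementField) -> AnalyticDVF:
    """Oracle displacement fields for validating the Jacobian metric.

    kinds: ``affine`` (u = A x + b; closed-form J = det(I+A)),
    ``gravity_gradient`` (u along a unit direction, quadratic in the
    coordinate along it; closed-form J linear in that coordinate),
    ``smooth_random`` (seeded B-spline field; no closed form).
    """
    shape, spacing, origin = grid.shape, grid.spacing_mm, grid.origin_mm
    pts = _grid_points(shape, spacing, origin)

    if kind == "affine":
        A = np.asarray(params["A"], dtype=float).reshape(3, 3)
        b = np.asarray(params.get("offset", np.zeros(3)), dtype=float).reshape(3)
        detj = float(np.linalg.det(np.eye(3) + A))
        if detj <= 0:
            raise FoldingError(f"affine field with det(I+A) = {detj:.4g} <= 0 is non-physical")
        u = pts @ A.T + b
        jac = lambda p: np.full(np.asarray(p).shape[:-1], detj)  # noqa: E731
    elif kind == "gravity_gradient":
        d = np.asarray(params["direction"], dtype=float).reshape(3)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("direction must be nonzero")
        d = d / nrm
        slope = float(params["slope"])          # per mm, d(strain)/ds
        base = float(params.get("base", 0.0))   # constant strain along d
        center = np.asarray(
            params.get("center", origin + spacing * (np.asarray(shape) - 1) / 2.0), dtype=float
        )
        s = (pts - center) @ d
        u = (base * s + 0.5 * slope * s**2)[..., None] * d

        def jac(p, _d=d, _c=center):
            sp = (np.asarray(p, dtype=float) - _c) @ _d
            j = 1.0 + base + slope * sp
            if np.any(j <= 0):
                raise FoldingError("gravity_gradient field folds within the queried points")
            return j

    elif kind == "smooth_random":
        amplitude = float(params.get("amplitude", 3.0))
        ctrl_spacing = float(params.get("control_spacing_mm", 24.0))
        rng = np.random.default_rng(int(params.get("seed", 0)))
        n_ctrl = [max(4, int(np.ceil(shape[a] * spacing[a] / ctrl_spacing)) + 3) for a in range(3)]
        coeffs = rng.normal(0.0, 1.0, size=(*n_ctrl, 3))
        # sample the control lattice with a cubic spline at every voxel
        u = np.empty(shape + (3,), dtype=float)
        coords = [
            (origin[a] + spacing[a] * np.arange(shape[a])) / ctrl_spacing + 1.0 for a in range(3)
        ]
        mesh = np.meshgrid(*coords, indexing="ij")
        for c in range(3):
            u[..., c] = ndimage.map_coordinates(
                coeffs[..., c], [m.ravel() for m in mesh], order=3, mode="nearest"
            ).reshape(shape)
        u *= amplitude / max(np.abs(u).max(), 1e-12)
        jac = None
    else:
        raise ValueError(f"unknown analytic field kind {kind!r}")

    fld = DisplacementField(vectors=u, spacing_mm=spacing, origin_mm=origin)
    return AnalyticDVF(field=fld, closed_form_jacobian=jac)


# ---------------------------------------------------------------------------
# phantom construction


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


class _Thorax:
    """Resolved phantom geometry and the analytic deformation machinery."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        shape = np.asarray(spec.grid_shape, dtype=int)
        spacing = np.asarray(spec.spacing_mm, dtype=float)
        extent = shape * spacing
        self.spacing = spacing
        self.shape = tuple(int(n) for n in shape)
        self.origin = spacing / 2.0  # voxel centres at (i + 1/2) * spacing
        self.center = extent / 2.0
        self.body_semi = extent * np.asarray(BODY_SEMI_FRAC)

        if spec.lung_geometry is None:
            semi = extent * np.asarray(LUNG_SEMI_FRAC)
            off = extent[0] * LUNG_OFFSET_FRAC
            left = self.center + np.array([off, 0.0, 0.0])
            right = self.center - np.array([off, 0.0, 0.0])
            self.lung_semi = semi
            self.lung_centers = {"left": left, "right": right}
        else:
            lg = spec.lung_geometry
            self.lung_semi = np.asarray(lg.semi_axes_mm, dtype=float)
            self.lung_centers = {
                "left": np.asarray(lg.left_center_mm, dtype=float),
                "right": np.asarray(lg.right_center_mm, dtype=float),
            }
        if spec.lungs == "left":
            self.lung_centers.pop("right")
        elif spec.lungs == "right":
            self.lung_centers.pop("left")

        self.spine_radius = 0.042 * extent[0]
        self.spine_y = self.center[1] + 0.58 * self.body_semi[1]
        self.spine_halfz = 0.85 * self.body_semi[2]

        self._validate_containment()
        self._setup_deformation()

    # -- geometry predicates (all vectorised over (..., 3) mm points) -------

    def body_radius(self, pts):
        d = (pts - self.center) / self.body_semi
        return np.sqrt(np.sum(d * d, axis=-1))

    def lung_label(self, pts):
        """0 background, 1 left lung, 2 right lung."""
        lab = np.zeros(np.asarray(pts).shape[:-1], dtype=np.uint8)
        for name, code in (("left", 1), ("right", 2)):
            if name in self.lung_centers:
                d = (pts - self.lung_centers[name]) / self.lung_semi
                lab[np.sum(d * d, axis=-1) <= 1.0] = code
        return lab

    def _validate_containment(self):
        # sample each lung surface and require it comfortably inside the
        # static envelope region of the body (r < ENVELOPE_INNER)
        th = np.linspace(0, np.pi, 24)
        ph = np.linspace(0, 2 * np.pi, 48)
        T, P = np.meshgrid(th, ph, indexing="ij")
        n = np.stack(
            [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
        )
        for name, c in self.lung_centers.items():
            surf = c + n * self.lung_semi
            r = self.body_radius(surf)
            if r.max() >= ENVELOPE_INNER - 0.005:
                raise ValueError(
                    f"{name} lung reaches body radius {r.max():.3f} >= {ENVELOPE_INNER}; "
                    "lungs must sit inside the static core of the body"
                )
        ext = np.asarray(self.shape) * self.spacing
        lo = self.center - self.body_semi
        hi = self.center + self.body_semi
        if np.any(lo < 0) or np.any(hi > ext):
            raise ValueError("body ellipsoid does not fit inside the image grid")

    # -- deformation ---------------------------------------------------------

    def _setup_deformation(self):
        spec = self.spec
        g = GRAVITY_VECTORS[spec.position]
        self.gravity = g
        self.g_axis = int(np.argmax(np.abs(g)))
        self.g_sign = float(np.sign(g[self.g_axis]))

        a = self.g_axis
        sgn = self.g_sign
        # lung band along gravity, in s = sgn * coordinate
        los, his = [], []
        for c in self.lung_centers.values():
            los.append(sgn * c[a] - self.lung_semi[a])
            his.append(sgn * c[a] + self.lung_semi[a])
        self.s0 = min(los)
        self.s1 = max(his)
        self.Lg = self.s1 - self.s0
        self.gamma = spec.gravity_gradient / self.Lg if self.Lg > 0 else 0.0

        # z (cranio-caudal) anchoring: symmetric stretch about the lung
        # z-centre, ramping to the static shell beyond both lung ends
        zc = [c[2] for c in self.lung_centers.values()]
        self.z_top = max(zc) + self.lung_semi[2]
        self.z_bot = min(zc) - self.lung_semi[2]
        self.z_mid = 0.5 * (self.z_top + self.z_bot)
        self.z_low = self.center[2] - ENVELOPE_INNER * self.body_semi[2]
        # diaphragm-ward modulation m_c: expansion additionally increases
        # toward the lung base (diaphragm breathing), spanning
        # CAUDAL_SHARE * gravity_gradient across the lung z-extent; tied to
        # gravity_gradient so a zero gradient still gives a constant Jacobian
        lz = self.z_top - self.z_bot
        self.gamma_c = CAUDAL_SHARE * spec.gravity_gradient / lz if lz > 0 else 0.0

        # means of the linear modulations over the lung union (both linear,
        # so ellipsoid averages equal the values at the lung centroids)
        cent = [1.0 + self.gamma * (sgn * c[a] - self.s0) for c in self.lung_centers.values()]
        self.mean_m = float(np.mean(cent))
        self.mean_mc = float(np.mean(
            [1.0 + self.gamma_c * (self.z_top - c[2]) for c in self.lung_centers.values()]
        ))

        target = spec.global_expansion / (self.mean_m * self.mean_mc)

        def f(k):
            return (1.0 + k) ** 2 * (1.0 + ANISOTROPY * k) - target

        self.k = brentq(f, -0.45, 4.0, xtol=1e-12)
        if abs(self.k) < 1e-12:
            self.k = 0.0
        self.kz = ANISOTROPY * self.k

        # s-band ramp ends at the static shell along the gravity axis
        self.s_lo_end = sgn * self.center[a] - ENVELOPE_INNER * self.body_semi[a]
        self.s_hi_end = sgn * self.center[a] + ENVELOPE_INNER * self.body_semi[a]
        # anti-gravity displacement anchor: supine anchors at the dependent
        # edge (all motion ventral); laterals split symmetrically
        self.beta = 1.0 if spec.position == "supine" else 0.5

        # prone lateral-stretch band along x and its ramp to the shell
        xs = [abs(c[0] - self.center[0]) for c in self.lung_centers.values()]
        self.x_band = max(xs) + self.lung_semi[0]
        self.x_shell = ENVELOPE_INNER * self.body_semi[0]

        # prone u_x taper along y beyond the lung band
        self.yband = self.lung_semi[1] + 2.0
        self.ytaper = 0.65 * self.lung_semi[1]
        # axis pair of the anti-gravity displacement's cross-section
        self.q_axis_b = 1 - self.g_axis  # the other horizontal axis
        # prone lateral stretch taper along z outside the lung z-band
        self.z_hi_end = self.center[2] + ENVELOPE_INNER * self.body_semi[2]

    def _m(self, s):
        # linear modulation, extended KINK_MARGIN_MM beyond the lung band so
        # the clip kinks sit away from the lung surfaces
        return 1.0 + self.gamma * np.clip(
            s - self.s0, -KINK_MARGIN_MM, self.Lg + KINK_MARGIN_MM
        )

    def _q(self, s):
        """Anti-gravity displacement along the gravity axis and its derivative.

        The quadratic segment extends KINK_MARGIN_MM beyond the lung band
        (keeping the field analytic near the lung surfaces); linear ramps
        then bring it to zero at the static shell.
        """
        k, gam, beta, L = self.k, self.gamma, self.beta, self.Lg
        lo, hi = self.s_lo_end, self.s_hi_end
        sq_lo = max(self.s0 - KINK_MARGIN_MM, lo + 1e-6)
        sq_hi = min(self.s1 + KINK_MARGIN_MM, hi - 1e-6)

        def quad(sv):
            return (1.0 + k) * gam * ((sv - self.s0) ** 2 - beta * L**2) / 2.0

        q = np.zeros_like(s)
        dq = np.zeros_like(s)
        band = (s >= sq_lo) & (s <= sq_hi)
        q[band] = quad(s[band])
        dq[band] = (1.0 + k) * gam * (s[band] - self.s0)
        below = (s < sq_lo) & (s > lo)
        if sq_lo > lo:
            q_lo = quad(np.array(sq_lo))
            q[below] = q_lo * (s[below] - lo) / (sq_lo - lo)
            dq[below] = q_lo / (sq_lo - lo)
        above = (s > sq_hi) & (s < hi)
        if hi > sq_hi:
            q_hi = quad(np.array(sq_hi))
            q[above] = q_hi * (hi - s[above]) / (hi - sq_hi)
            dq[above] = -q_hi / (hi - sq_hi)
        return q, dq

    def _mc(self, z):
        """Diaphragm-ward modulation: expansion grows toward the lung base."""
        return 1.0 + self.gamma_c * np.clip(self.z_top - z, 0.0, self.z_top - self.z_bot)

    def _zstretch(self, z, amp):
        """Cranio-caudal displacement U(z) with strain amp·m_c(z) − 1 inside
        the lung z-band, anchored at the band centre and ramping linearly to
        zero at the static shell beyond both lung ends.

        ``amp`` may be an array (prone modulates it by m(s)); returns
        (U, dU/dz).
        """
        zm, zt, zb, gc = self.z_mid, self.z_top, self.z_bot, self.gamma_c
        amp = np.asarray(amp, dtype=float)
        amp_b = np.broadcast_to(amp, np.shape(z)) if amp.ndim else amp

        def G(zv):  # ∫ m_c dz from z_mid, for z within the band
            return (zv - zm) + gc * (zt * (zv - zm) - (zv**2 - zm**2) / 2.0)

        U = np.zeros_like(z)
        dU = np.zeros_like(z)
        band = (z >= zb) & (z <= zt)
        ampv = amp_b[band] if amp.ndim else amp
        U[band] = ampv * G(z[band]) - (z[band] - zm)
        dU[band] = ampv * self._mc(z[band]) - 1.0

        u_top = amp * G(np.array(zt)) - (zt - zm)   # scalar or full-shape
        u_bot = amp * G(np.array(zb)) - (zb - zm)
        hi_w = self.z_hi_end - zt
        above = (z > zt) & (z < self.z_hi_end)
        if hi_w > 0:
            ut = np.broadcast_to(u_top, np.shape(z))[above] if amp.ndim else u_top
            U[above] = ut * (self.z_hi_end - z[above]) / hi_w
            dU[above] = -ut / hi_w
        lo_w = zb - self.z_low
        below = (z < zb) & (z > self.z_low)
        if lo_w > 0:
            ub = np.broadcast_to(u_bot, np.shape(z))[below] if amp.ndim else u_bot
            U[below] = ub * (z[below] - self.z_low) / lo_w
            dU[below] = ub / lo_w
        return U, dU

    def _union_taper(self, pts, axes: tuple[int, int], decay: float):
        """Smooth weight = 1 over the lungs' cross-section in the given axis
        pair (per-lung ellipses with 2 mm margin, union via min), decaying to
        0 outside.  Unity on the lung union keeps in-lung strains exact."""
        rho = None
        for c in self.lung_centers.values():
            da = pts[..., axes[0]] - c[axes[0]]
            db = pts[..., axes[1]] - c[axes[1]]
            r = np.sqrt(
                (da / (self.lung_semi[axes[0]] + 2.0)) ** 2
                + (db / (self.lung_semi[axes[1]] + 2.0)) ** 2
            )
            rho = r if rho is None else np.minimum(rho, r)
        return 1.0 - _smoothstep((rho - 1.0) / decay)

    def _footprint(self, pts):
        """Lateral (x, y) footprint of the cranio-caudal stretch."""
        return self._union_taper(pts, (0, 1), FOOT_DECAY)

    def _qfootprint(self, pts):
        """Cross-sectional confinement of the anti-gravity displacement."""
        return self._union_taper(pts, (self.q_axis_b, 2), QFOOT_DECAY)

    def _ztaper(self, z):
        """Unity on the lung z-band, smooth decay to the static shell."""
        lo_w = max(self.z_bot - self.z_low, 1e-6)
        hi_w = max(self.z_hi_end - self.z_top, 1e-6)
        below = np.clip((self.z_bot - 2.0 - z) / lo_w, 0.0, None)
        above = np.clip((z - self.z_top - 2.0) / hi_w, 0.0, None)
        return 1.0 - _smoothstep(np.maximum(below, above))

    def _envelope(self, pts):
        r = self.body_radius(pts)
        return 1.0 - _smoothstep((r - ENVELOPE_INNER) / (1.0 - ENVELOPE_INNER))

    def displacement(self, pts):
        """Full displacement u(points) in mm, zero outside the body."""
        u, _ = self._triangular(pts)
        w = self._envelope(pts)
        return u * w[..., None]

    def _triangular(self, pts):
        """Core (pre-envelope) field and its diagonal strain factors."""
        spec = self.spec
        c = self.center
        dx = pts[..., 0] - c[0]
        dy = pts[..., 1] - c[1]
        z = pts[..., 2]
        a, sgn = self.g_axis, self.g_sign
        s = sgn * pts[..., a]
        k, kz = self.k, self.kz

        u = np.zeros_like(pts, dtype=float)
        diag = np.empty(pts.shape[:-1] + (3,), dtype=float)

        lam = self._footprint(pts)

        if spec.position == "prone":
            # gravity modulation split between lateral (x) and cranio-caudal
            # (z) stretch, both parallel to the ground: the shares multiply back to m
            m = self._m(s)
            cx = (1.0 + k) * m**PRONE_X_SHARE - 1.0
            U, dU = self._zstretch(z, (1.0 + kz) * m ** (1.0 - PRONE_X_SHARE))
            # lateral stretch: linear in x inside the band, ramped to the shell
            X = np.clip(np.abs(dx), None, self.x_band)
            ramp = np.clip((self.x_shell - np.abs(dx)) / (self.x_shell - self.x_band), 0.0, 1.0)
            X = np.where(np.abs(dx) > self.x_band, self.x_band * ramp, X)
            dX = np.where(
                np.abs(dx) > self.x_band,
                np.where(np.abs(dx) < self.x_shell, -self.x_band / (self.x_shell - self.x_band), 0.0),
                1.0,
            )
            lamx = (1.0 - _smoothstep((np.abs(dy) - self.yband) / self.ytaper)) * self._ztaper(z)
            u[..., 0] = cx * np.sign(dx) * X * lamx
            u[..., 1] = k * dy
            u[..., 2] = U * lam
            diag[..., 0] = 1.0 + cx * dX * lamx
            diag[..., 1] = 1.0 + k
            diag[..., 2] = 1.0 + dU * lam
        else:
            q, dq = self._q(s)
            lamq = self._qfootprint(pts)
            U, dU = self._zstretch(z, 1.0 + kz)
            u[..., 0] = k * dx
            u[..., 1] = k * dy
            u[..., a] += sgn * q * lamq
            u[..., 2] = U * lam
            diag[..., 0] = 1.0 + k
            diag[..., 1] = 1.0 + k
            diag[..., a] += dq * lamq
            diag[..., 2] = 1.0 + dU * lam
        return u, diag

    def jacobian_closed_form(self, pts):
        """Exact Jacobian of the core field (valid wherever the envelope = 1,
        in particular everywhere inside the lungs)."""
        _, diag = self._triangular(pts)
        return diag[..., 0] * diag[..., 1] * diag[..., 2]

    def inverse_map(self, pts, n_iter: int = 30):
        """Solve x + u(x) = y for x by fixed-point iteration."""
        x = pts.copy()
        for _ in range(n_iter):
            x = pts - self.displacement(x)
        return x

    # -- rendering -----------------------------------------------------------

    def _edge(self, rho, scale_mm):
        """Smooth inside-fraction of an implicit surface rho = 1.

        Emulates the scanner point-spread function: the interface spans
        ~``PV_WIDTH_MM`` physically (rho is converted to mm via the shape's
        characteristic radius), and, being analytic, it is rendered
        identically in both breathing phases.
        """
        t = (1.0 - rho) * scale_mm / PV_WIDTH_MM + 0.5
        return _smoothstep(t)

    def render_hu(self, pts, texture=None):
        hu_def = self.spec.tissue_hu
        s_body = self._edge(self.body_radius(pts), float(np.mean(self.body_semi)))
        hu = hu_def.air + (hu_def.soft - hu_def.air) * s_body

        dxy = np.sqrt(
            (pts[..., 0] - self.center[0]) ** 2 + (pts[..., 1] - self.spine_y) ** 2
        )
        s_spine = self._edge(dxy / self.spine_radius, self.spine_radius)
        s_spine = s_spine * self._edge(
            np.abs(pts[..., 2] - self.center[2]) / self.spine_halfz, self.spine_halfz
        )
        hu += (hu_def.spine - hu_def.soft) * s_spine * s_body

        lung_scale = float(np.mean(self.lung_semi))
        s_lung = np.zeros(pts.shape[:-1])
        for c in self.lung_centers.values():
            d = (pts - c) / self.lung_semi
            rho = np.sqrt(np.sum(d * d, axis=-1))
            s_lung = np.maximum(s_lung, self._edge(rho, lung_scale))
        lung_hu = np.full(pts.shape[:-1], hu_def.lung)
        if texture is not None and self.spec.texture_sd_hu > 0:
            # texture is a prefiltered cubic-spline coefficient grid: both
            # phases sample the same smooth continuous function, so neither
            # rendering is sharper than the other
            idx = (pts - self.origin) / self.spacing
            lung_hu += ndimage.map_coordinates(
                texture,
                [idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()],
                order=3,
                prefilter=False,
                mode="nearest",
            ).reshape(pts.shape[:-1])
        hu += (lung_hu - hu_def.soft) * s_lung * s_body
        return hu


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render a deterministic exhale/inhale pair with ground-truth DVF.

    Raises :class:`FoldingError` if the requested deformation would fold
    (ground-truth Jacobian ≤ 0.05 anywhere in the body).
    """
    thorax = _Thorax(spec)
    rng = np.random.default_rng(spec.seed)
    pts = _grid_points(thorax.shape, thorax.spacing, thorax.origin)

    # ground-truth displacement on the exhale grid
    uvec = thorax.displacement(pts)
    truth_dvf = DisplacementField(
        vectors=uvec, spacing_mm=thorax.spacing, origin_mm=thorax.origin
    )

    jac_fd = jacobian_map(truth_dvf)
    body = thorax.body_radius(pts) <= 1.0
    jmin = float(jac_fd.data[body].min()) if body.any() else 1.0
    if jmin <= 0.01:
        raise FoldingError(
            f"deformation folds: min Jacobian in body = {jmin:.3f} "
            f"(expansion {spec.global_expansion}, gradient {spec.gravity_gradient})"
        )

    # lung texture (material coordinates of the exhale phase): two spatial
    # scales, mimicking fine parenchymal grain plus coarser vascular trees
    texture = None
    if spec.texture_sd_hu > 0:
        base = rng.standard_normal(thorax.shape)
        texture = np.zeros(thorax.shape)
        for scale, power in ((1.0, 0.5), (2.5, 0.5)):
            sigma = scale * spec.texture_corr_mm / thorax.spacing
            comp = ndimage.gaussian_filter(base, sigma=sigma)
            sd = comp.std()
            if sd > 0:
                texture += np.sqrt(power) * spec.texture_sd_hu * comp / sd
        # store as cubic-spline coefficients of a continuous texture function
        texture = ndimage.spline_filter(texture, order=3, mode="nearest")

    exhale_hu = thorax.render_hu(pts, texture)

    identity_motion = thorax.k == 0.0 and thorax.gamma == 0.0
    if identity_motion:
        inhale_hu = exhale_hu.copy()
        lab_in = thorax.lung_label(pts)
    else:
        back = thorax.inverse_map(pts)
        inhale_hu = thorax.render_hu(back, texture)
        lab_in = thorax.lung_label(back)
        if spec.density_rescale:
            # gas dilution: expanded parenchyma gets darker by 1/J
            airlike = (inhale_hu < -400.0) & (thorax.body_radius(back) <= 1.0)
            jb = thorax.jacobian_closed_form(back[airlike])
            inhale_hu[airlike] = -1000.0 + (inhale_hu[airlike] + 1000.0) / jb

    if spec.noise_sd_hu > 0:
        exhale_hu = exhale_hu + rng.normal(0.0, spec.noise_sd_hu, thorax.shape)
        inhale_hu = inhale_hu + rng.normal(0.0, spec.noise_sd_hu, thorax.shape)

    lab_ex = thorax.lung_label(pts)
    geom = dict(spacing_mm=thorax.spacing, origin_mm=thorax.origin)
    lungs_mask = lab_ex > 0
    mean_j_lung = float(jac_fd.data[lungs_mask].mean()) if lungs_mask.any() else np.nan

    meta = {
        "k_transverse": thorax.k,
        "k_craniocaudal": thorax.kz,
        "gamma_per_mm": thorax.gamma,
        "mean_modulation": thorax.mean_m,
        "mean_truth_jacobian_lung": mean_j_lung,
        "min_truth_jacobian_body": jmin,
        "exhale_lung_voxels": int(lungs_mask.sum()),
        "inhale_lung_voxels": int((lab_in > 0).sum()),
    }

    return PhantomPair(
        exhale=ImageVolume(data=exhale_hu, **geom),
        inhale=ImageVolume(data=inhale_hu, **geom),
        truth_dvf=truth_dvf,
        truth_lungs=ImageVolume(data=lab_ex, **geom),
        truth_lungs_inhale=ImageVolume(data=lab_in, **geom),
        gravity_unit_vector=GRAVITY_VECTORS[spec.position].copy(),
        spec=spec,
        meta=meta,
    )
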