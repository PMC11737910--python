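"""B-spline deformable registration of breath-hold CT pairs.

The expiration-phase image is the fixed reference; registration estimates
the dense displacement field u (mm, on the fixed grid) such that
``moving(x + u(x)) ≈ fixed(x)``, i.e. u points from the expiration
position of a tissue element to its inspiration position.

The transform is a free-form deformation parameterised by cubic B-spline
coefficients on a coarse control lattice,

    u(x) = Σ_j c_j · β³((x − x_j) / h),

optimised coarse-to-fine: the control spacing h halves per pyramid level
while the images are smoothed and subsampled, and each level adds a
residual deformation on top of the field accumulated so far.  Within a
level the objective

    E(c) = metric(fixed, moving ∘ (id + u)) + λ · bend(c)

(metric: mean squared HU difference, or one minus normalised
cross-correlation; bend: squared second differences of the control
coefficients) is minimised by L-BFGS-B with an analytic gradient (the adjoint of the
B-spline lattice applied to the metric force), so the recorded objective
is non-increasing across accepted iterations and the whole procedure is
deterministic — no random sampling, no seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .imageio import DisplacementField, ImageVolume, require_same_grid

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "RegistrationError",
    "register_bspline",
    "warp",
    "bending_energy",
]


class RegistrationError(RuntimeError):
    """Registration could not run or did not improve the similarity metric."""

    def __init__(self, message: str, level: int | None = None):
        super().__init__(message)
        self.level = level


@dataclass(frozen=True)
class RegistrationConfig:
    """Settings of the multi-resolution B-spline registration.

    Per pyramid level (coarse to fine): ``shrink_factors`` subsample the
    images, ``smoothing_sigmas`` (voxels, applied before subsampling)
    suppress aliasing, ``control_spacing_mm`` sets the B-spline knot
    spacing (snapped to an integer multiple of the level voxel spacing)
    and ``max_iterations`` caps the descent steps.  ``metric`` is ``ssd``
    (mono-modal CT default) or ``ncc``; ``bending_weight`` scales the
    control-lattice bending penalty.
    """

    pyramid_levels: int = 2
    control_spacing_mm: tuple[float, ...] = (48.0, 32.0)
    shrink_factors: tuple[int, ...] = (4, 2)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0)
    metric: str = "ssd"
    bending_weight: float = 1.0
    max_iterations: tuple[int, ...] = (200, 250)
    convergence_tol: float = 1e-9
    interpolation: str = "linear"
    folding_guard: float = 0.05

    def __post_init__(self):
        if self.metric not in ("ssd", "ncc", "sstvd"):
            raise ValueError(
                f"metric must be 'ssd', 'ncc' or 'sstvd', got {self.metric!r}"
            )
        if self.interpolation not in ("linear", "cubic"):
            raise ValueError(
                f"interpolation must be 'linear' or 'cubic', got {self.interpolation!r}"
            )
        n = self.pyramid_levels
        if isinstance(self.max_iterations, int):
            object.__setattr__(self, "max_iterations", (self.max_iterations,) * n)
        if not (
            len(self.control_spacing_mm) == len(self.shrink_factors)
            == len(self.smoothing_sigmas) == len(self.max_iterations) == n
        ):
            raise ValueError(
                "control_spacing_mm, shrink_factors, smoothing_sigmas and "
                f"max_iterations must all have pyramid_levels = {n} entries"
            )
        if self.bending_weight < 0:
            raise ValueError("bending_weight must be >= 0")
        if any(
            self.control_spacing_mm[i] < self.control_spacing_mm[i + 1]
            for i in range(n - 1)
        ):
            raise ValueError("control_spacing_mm must be non-increasing (coarse to fine)")

    def validate_against(self, volume: ImageVolume) -> None:
        min_cs = min(self.control_spacing_mm)
        if min_cs < 2.0 * max(volume.spacing_mm):
            raise ValueError(
                f"finest control spacing {min_cs} mm must be at least twice "
                f"the voxel spacing {tuple(volume.spacing_mm)} mm"
            )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=lambda o: list(o))

    @staticmethod
    def from_json(text: str) -> "RegistrationConfig":
        d = json.loads(text)
        for key in ("control_spacing_mm", "shrink_factors", "smoothing_sigmas", "max_iterations"):
            if key in d and not isinstance(d[key], int):
                d[key] = tuple(d[key])
        return RegistrationConfig(**d)


@dataclass
class RegistrationResult:
    dvf: DisplacementField
    final_metric: float
    level_iterations: list[int]
    metric_history: list[list[float]]  # accepted-step metric values per level
    min_jacobian: float = float("nan")


# ---------------------------------------------------------------------------
# cubic B-spline lattice machinery


def _bspline3(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    near = at < 1.0
    far = (at >= 1.0) & (at < 2.0)
    out[near] = 2.0 / 3.0 - at[near] ** 2 + at[near] ** 3 / 2.0
    out[far] = (2.0 - at[far]) ** 3 / 6.0
    return out


def _bspline3_deriv(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    sgn = np.sign(t)
    out = np.zeros_like(at)
    near = at < 1.0
    far = (at >= 1.0) & (at < 2.0)
    out[near] = sgn[near] * (1.5 * at[near] ** 2 - 2.0 * at[near])
    out[far] = sgn[far] * (-0.5 * (2.0 - at[far]) ** 2)
    return out


class _Lattice:
    """Cubic B-spline control lattice aligned with a voxel grid.

    The knot spacing is ``stride`` voxels (integer); knot j along an axis
    sits at voxel index (j − margin) * stride, with ``margin`` extra knots
    on each side so every voxel has full 4-knot support.
    """

    MARGIN = 2

    def __init__(
        self,
        shape: tuple[int, int, int],
        stride: tuple[int, int, int],
        n_ctrl: tuple[int, int, int] | None = None,
    ):
        self.shape = shape
        self.stride = stride
        self.n_ctrl = n_ctrl or tuple(
            int(np.ceil((shape[a] - 1) / stride[a])) + 1 + 2 * self.MARGIN for a in range(3)
        )
        self.kernels = [
            _bspline3(np.arange(-2 * stride[a], 2 * stride[a] + 1) / stride[a])
            for a in range(3)
        ]
        # working-grid size: must hold every strided knot position and the
        # padded voxel block, so evaluate/project stay exact transposes
        self._pad = tuple(self.MARGIN * stride[a] for a in range(3))
        self._gsize = tuple(
            max((self.n_ctrl[a] - 1) * stride[a] + 1, shape[a] + 2 * self._pad[a])
            for a in range(3)
        )
        self._knot_sl = tuple(
            slice(0, (self.n_ctrl[a] - 1) * stride[a] + 1, stride[a]) for a in range(3)
        )
        self._vox_sl = tuple(
            slice(self._pad[a], self._pad[a] + shape[a]) for a in range(3)
        )

    def coeff_shape(self) -> tuple[int, ...]:
        return (*self.n_ctrl, 3)

    def set_voxel_mm(self, voxel_mm) -> None:
        """Attach physical voxel size so spatial-derivative kernels are in mm⁻¹."""
        self.deriv_kernels = [
            _bspline3_deriv(np.arange(-2 * self.stride[a], 2 * self.stride[a] + 1) / self.stride[a])
            / (self.stride[a] * voxel_mm[a])
            for a in range(3)
        ]

    def _eval_kernels(self, coeff_comp: np.ndarray, kernels) -> np.ndarray:
        grid = np.zeros(self._gsize)
        grid[self._knot_sl] = coeff_comp
        for a in range(3):
            grid = ndimage.convolve1d(grid, kernels[a], axis=a, mode="constant")
        return grid[self._vox_sl]

    def _project_kernels(self, dense_scalar: np.ndarray, kernels) -> np.ndarray:
        # correlate1d is the exact transpose of convolve1d for any kernel
        grid = np.zeros(self._gsize)
        grid[self._vox_sl] = dense_scalar
        for a in range(3):
            grid = ndimage.correlate1d(grid, kernels[a], axis=a, mode="constant")
        return grid[self._knot_sl]

    def evaluate(self, coeffs: np.ndarray) -> np.ndarray:
        """Dense field on the voxel grid: u = Σ_j c_j β³((x − x_j)/h)."""
        out = np.empty((*self.shape, 3))
        for comp in range(3):
            out[..., comp] = self._eval_kernels(coeffs[..., comp], self.kernels)
        return out

    def project(self, dense: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`evaluate`: scatter a dense (…, 3) field onto
        the control coefficients (exact transpose)."""
        out = np.empty(self.coeff_shape())
        for comp in range(3):
            out[..., comp] = self._project_kernels(dense[..., comp], self.kernels)
        return out

    def _dk(self, axis: int):
        k = list(self.kernels)
        k[axis] = self.deriv_kernels[axis]
        return k

    def evaluate_grad(self, coeffs: np.ndarray) -> np.ndarray:
        """Exact spatial gradient of the field: (…, i, j) = ∂u_i/∂x_j (mm/mm)."""
        out = np.empty((*self.shape, 3, 3))
        for comp in range(3):
            for axis in range(3):
                out[..., comp, axis] = self._eval_kernels(coeffs[..., comp], self._dk(axis))
        return out

    def project_grad(self, dense: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`evaluate_grad` for a dense (…, 3, 3) field."""
        out = np.zeros(self.coeff_shape())
        for comp in range(3):
            for axis in range(3):
                out[..., comp] += self._project_kernels(dense[..., comp, axis], self._dk(axis))
        return out


def _bend_penalty(
    coeffs: np.ndarray, knot_mm: tuple[float, float, float]
) -> tuple[float, np.ndarray]:
    """Physically scaled curvature penalty on the control lattice.

    Second differences of the coefficients divided by the squared knot
    spacing approximate ∂²u/∂x² (mm⁻¹); their squares are integrated over
    knot cells (h_x·h_y·h_z), making the penalty comparable across pyramid
    levels — coarse, smooth deformations are cheap while voxel-scale
    wiggles on a fine lattice are expensive.
    """
    vol = float(np.prod(knot_mm))
    value = 0.0
    grad = np.zeros_like(coeffs)
    for a in range(3):
        scale = vol / knot_mm[a] ** 4  # (1/h²)² integrated over cells
        d2 = np.diff(coeffs, n=2, axis=a)
        value += scale * float(np.sum(d2**2))
        # adjoint of the second difference: correlate with [1, -2, 1]
        g = np.zeros_like(coeffs)
        sl = [slice(None)] * coeffs.ndim
        for off, w in ((0, 1.0), (1, -2.0), (2, 1.0)):
            sl[a] = slice(off, coeffs.shape[a] - 2 + off)
            g[tuple(sl)] += w * d2
        grad += (2.0 * scale) * g
    return value, grad


# ---------------------------------------------------------------------------
# metric and pyramid helpers


def _ssd(fixed: np.ndarray, warped: np.ndarray, roi: np.ndarray | None) -> tuple[float, np.ndarray]:
    r = warped - fixed
    if roi is not None:
        r = r * roi
        n = max(int(roi.sum()), 1)
    else:
        n = r.size
    return float(np.sum(r * r) / n), (2.0 / n) * r


def _ncc(fixed: np.ndarray, warped: np.ndarray, roi: np.ndarray | None) -> tuple[float, np.ndarray]:
    if roi is None:
        roi = np.ones_like(fixed)
    n = max(int(roi.sum()), 1)
    fm = float((fixed * roi).sum() / n)
    wm = float((warped * roi).sum() / n)
    f = (fixed - fm) * roi
    w = (warped - wm) * roi
    sf = np.sqrt(np.sum(f**2))
    sw = np.sqrt(np.sum(w**2))
    if sf == 0 or sw == 0:
        return 1.0, np.zeros_like(warped)
    corr = float(np.sum(f * w) / (sf * sw))
    grad = -(f / (sf * sw) - corr * w / sw**2) * roi
    return 1.0 - corr, grad


def _downsample(data: np.ndarray, shrink: int, sigma: float) -> np.ndarray:
    if sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=sigma)
    if shrink > 1:
        data = data[::shrink, ::shrink, ::shrink]
    return data


def _sample(img: np.ndarray, coords_vox: list[np.ndarray], cval: float = -1000.0) -> np.ndarray:
    # grid-constant: out-of-domain values blend continuously toward cval
    return ndimage.map_coordinates(img, coords_vox, order=1, mode="grid-constant", cval=cval)


def register_bspline(
    fixed: ImageVolume,
    moving: ImageVolume,
    config: RegistrationConfig | None = None,
    roi: np.ndarray | ImageVolume | None = None,
    initial_dvf: DisplacementField | None = None,
) -> RegistrationResult:
    """Estimate the exhale→inhale displacement field on the fixed grid.

    ``roi`` optionally restricts the similarity metric to a mask on the
    fixed grid (conventionally the lungs plus a margin, as in lung-masked
    DIR); the B-spline extrapolates smoothly outside.  Deterministic:
    identical inputs and config give an identical field.  Raises
    :class:`RegistrationError` for non-overlapping fields of view and
    flags (via ``folding_guard``) estimates that fold.
    """
    config = config or RegistrationConfig()
    config.validate_against(fixed)

    lo_f = fixed.origin_mm
    hi_f = fixed.origin_mm + fixed.spacing_mm * (np.asarray(fixed.shape) - 1)
    lo_m = moving.origin_mm
    hi_m = moving.origin_mm + moving.spacing_mm * (np.asarray(moving.shape) - 1)
    if np.any(np.maximum(lo_f, lo_m) >= np.minimum(hi_f, hi_m)):
        raise RegistrationError("fixed and moving fields of view do not overlap")
    require_same_grid(fixed, moving, "fixed and moving volumes")

    metric_fn = {"ssd": _ssd, "ncc": _ncc, "sstvd": None}[config.metric]
    fdata = np.asarray(fixed.data, dtype=float)
    mdata = np.asarray(moving.data, dtype=float)
    if roi is not None:
        if isinstance(roi, ImageVolume):
            roi = np.asarray(roi.data)
        roi = (np.asarray(roi) != 0).astype(float)
        if roi.shape != fixed.shape:
            raise RegistrationError(f"roi shape {roi.shape} does not match fixed {fixed.shape}")
        if not roi.any():
            raise RegistrationError("roi mask is empty")

    if initial_dvf is not None:
        require_same_grid(fixed, initial_dvf, "fixed volume and initial field")
        u_full = np.array(initial_dvf.vectors, dtype=float)
    else:
        u_full = np.zeros((*fixed.shape, 3))
    history: list[list[float]] = []
    level_iters: list[int] = []

    for lvl in range(config.pyramid_levels):
        shrink = int(config.shrink_factors[lvl])
        sigma = float(config.smoothing_sigmas[lvl])
        f_l = _downsample(fdata, shrink, sigma)
        m_l = _downsample(mdata, shrink, sigma)
        roi_l = None
        if roi is not None:
            roi_l = _downsample(roi, shrink, sigma)  # soft edge after smoothing
        spacing_l = fixed.spacing_mm * shrink
        shape_l = f_l.shape

        # knot spacing snapped to an integer number of level voxels (>= 2)
        stride = tuple(
            max(2, int(round(config.control_spacing_mm[lvl] / spacing_l[a]))) for a in range(3)
        )
        lattice = _Lattice(shape_l, stride)
        lattice.set_voxel_mm(spacing_l)
        knot_mm = tuple(stride[a] * spacing_l[a] for a in range(3))
        coeffs = np.zeros(lattice.coeff_shape())

        # base field accumulated from coarser levels, on this level's grid
        u_base = u_full[::shrink, ::shrink, ::shrink]
        idx = np.indices(shape_l, dtype=float)

        # forward differences: exact derivative of the trilinear interpolant
        m_diff = [np.diff(m_l, axis=a) / spacing_l[a] for a in range(3)]

        def sample_moving_grad(coords):
            dense = np.empty((*shape_l, 3))
            for a in range(3):
                # sample the cell-wise slope: integer coordinate along axis a
                ca = list(coords)
                ca[a] = np.clip(np.floor(coords[a]), 0, shape_l[a] - 2)
                dense[..., a] = _sample(m_diff[a], ca, cval=0.0)
            return dense

        if config.metric == "sstvd":
            # gradient of the accumulated base field (fixed within the level)
            g_base = np.zeros((*shape_l, 3, 3))
            for i in range(3):
                for j in range(3):
                    g_base[..., i, j] = np.gradient(u_base[..., i], spacing_l[j], axis=j)
            n_m = float(roi_l.sum()) if roi_l is not None else float(f_l.size)
            v_f = f_l + 1000.0

            def objective(c):
                u = u_base + lattice.evaluate(c)
                coords = [idx[a] + u[..., a] / spacing_l[a] for a in range(3)]
                warped = _sample(m_l, coords)
                A = g_base + lattice.evaluate_grad(c)
                A[..., 0, 0] += 1.0
                A[..., 1, 1] += 1.0
                A[..., 2, 2] += 1.0
                jac = (
                    A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
                    - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
                    + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
                )
                r = (warped + 1000.0) * jac - v_f
                if roi_l is not None:
                    r = r * roi_l
                value = float(np.sum(r * r) / n_m)
                bend_v, bend_g = _bend_penalty(c, knot_mm)
                aux = (coords, r, warped, A, jac, bend_g)
                return value + config.bending_weight * bend_v, aux, value

            def gradient(c, aux):
                coords, r, warped, A, jac, bend_g = aux
                w = (2.0 / n_m) * r
                # intensity term: d/du of warped, weighted by J
                dense = sample_moving_grad(coords) * (w * jac)[..., None]
                grad = lattice.project(dense)
                # volume term: dJ/dA is the cofactor matrix of A
                cof = np.empty_like(A)
                cof[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
                cof[..., 0, 1] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
                cof[..., 0, 2] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
                cof[..., 1, 0] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
                cof[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
                cof[..., 1, 2] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
                cof[..., 2, 0] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
                cof[..., 2, 1] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
                cof[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
                cof *= (w * (warped + 1000.0))[..., None, None]
                grad += lattice.project_grad(cof)
                return grad + config.bending_weight * bend_g

        else:

            def objective(c):
                u = u_base + lattice.evaluate(c)
                coords = [idx[a] + u[..., a] / spacing_l[a] for a in range(3)]
                warped = _sample(m_l, coords)
                value, dmetric = metric_fn(f_l, warped, roi_l)
                bend_v, bend_g = _bend_penalty(c, knot_mm)
                return value + config.bending_weight * bend_v, (coords, dmetric, bend_g), value

            def gradient(c, aux):
                coords, dmetric, bend_g = aux
                dense = sample_moving_grad(coords) * dmetric[..., None]
                return lattice.project(dense) + config.bending_weight * bend_g

        cshape = lattice.coeff_shape()
        last: dict = {}

        def fun(flat):
            c = flat.reshape(cshape)
            energy, aux, _ = objective(c)
            g = gradient(c, aux)
            last["x"] = flat.copy()
            last["f"] = energy
            return energy, g.ravel()

        e0, _, _ = objective(coeffs)
        hist = [e0]  # objective value (metric + bending term)

        def on_accept(xk):
            # L-BFGS-B evaluates f at xk right before accepting it
            if last.get("x") is not None and np.array_equal(last["x"], xk):
                hist.append(last["f"])

        opt = minimize(
            fun,
            coeffs.ravel(),
            jac=True,
            method="L-BFGS-B",
            callback=on_accept,
            options=dict(
                maxiter=int(config.max_iterations[lvl]),
                ftol=config.convergence_tol,
                gtol=1e-12,
                maxcor=8,
            ),
        )
        coeffs = opt.x.reshape(cshape)
        history.append(hist)
        level_iters.append(int(opt.nit))

        # promote this level's contribution to the full-resolution grid
        if shrink > 1:
            full_lattice = _Lattice(
                fixed.shape, tuple(s * shrink for s in stride), n_ctrl=lattice.n_ctrl
            )
            u_full = u_full + full_lattice.evaluate(coeffs)
        else:
            u_full = u_full + lattice.evaluate(coeffs)

    dvf = DisplacementField(
        vectors=u_full, spacing_mm=fixed.spacing_mm, origin_mm=fixed.origin_mm
    )
    from .ventilation import jacobian_map  # local import to avoid cycle

    min_jac = float(jacobian_map(dvf).data.min())
    result = RegistrationResult(
        dvf=dvf,
        final_metric=history[-1][-1] if history and history[-1] else float("nan"),
        level_iterations=level_iters,
        metric_history=history,
        min_jacobian=min_jac,
    )
    if config.folding_guard > 0 and min_jac <= config.folding_guard:
        raise RegistrationError(
            f"estimated field folds: min Jacobian {min_jac:.3f} <= guard "
            f"{config.folding_guard} (inputs are likely inconsistent)"
        )
    return result


def warp(
    volume: ImageVolume, dvf: DisplacementField, interpolation: str = "linear"
) -> ImageVolume:
    """Resample ``volume`` at position + u: output(x) = volume(x + u(x)).

    With the registration's displacement convention this pulls the moving
    (inspiration) image back onto the fixed (expiration) grid.  Samples
    outside the input domain take ambient-air HU (−1000).
    """
    require_same_grid(volume, dvf, "volume and displacement field")
    order = {"linear": 1, "cubic": 3}.get(interpolation)
    if order is None:
        raise ValueError(f"interpolation must be 'linear' or 'cubic', got {interpolation!r}")
    idx = np.indices(volume.shape, dtype=float)
    coords = [idx[a] + dvf.vectors[..., a] / volume.spacing_mm[a] for a in range(3)]
    data = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), coords, order=order, mode="grid-constant", cval=-1000.0
    )
    return volume.with_data(data)


def bending_energy(dvf: DisplacementField) -> float:
    """Discrete bending energy: ∫ Σ_{i,j,k} (∂²u_i/∂x_j∂x_k)² dV.

    Zero exactly for any affine field (second derivatives vanish).  Each
    second derivative of u carries mm⁻¹, so the integrand is mm⁻² and the
    voxel-volume-scaled sum has net units of mm; treat the value as a
    relative smoothness diagnostic.
    """
    total = 0.0
    for i in range(3):
        first = [
            np.gradient(dvf.vectors[..., i], dvf.spacing_mm[j], axis=j) for j in range(3)
        ]
        for j in range(3):
            for k in range(3):
                second = np.gradient(first[j], dvf.spacing_mm[k], axis=k)
                total += float(np.sum(second**2))
    return total * dvf.voxel_volume_mm3
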