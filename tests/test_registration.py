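import numpy as np
import pytest

from bhctvi import (
    DisplacementField,
    ImageVolume,
    PhantomSpec,
    RegistrationConfig,
    RegistrationError,
    analytic_dvf,
    bending_energy,
    generate_phantom,
    register_bspline,
    warp,
)
from bhctvi.phantom import _Thorax, _grid_points
from bhctvi.registration import _Lattice

FAST = RegistrationConfig(
    pyramid_levels=2, control_spacing_mm=(48.0, 24.0), shrink_factors=(4, 2),
    smoothing_sigmas=(2.0, 1.0), bending_weight=0.3, max_iterations=(80, 60),
)


@pytest.fixture(scope="module")
def coarse_pair():
    return generate_phantom(
        PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(4.0,) * 3,
                    noise_sd_hu=5.0, global_expansion=1.0, gravity_gradient=0.0, seed=2)
    )


class TestLattice:
    def test_evaluate_project_are_exact_adjoints(self):
        rng = np.random.default_rng(0)
        lat = _Lattice((20, 18, 17), (4, 4, 4))
        c = rng.normal(size=lat.coeff_shape())
        d = rng.normal(size=(20, 18, 17, 3))
        assert np.sum(lat.evaluate(c) * d) == pytest.approx(np.sum(c * lat.project(d)))

    def test_partition_of_unity(self):
        lat = _Lattice((12, 12, 12), (3, 3, 3))
        u = lat.evaluate(np.ones(lat.coeff_shape()))
        assert np.allclose(u, 1.0, atol=1e-12)

    def test_gradient_evaluation_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        lat = _Lattice((16, 16, 16), (4, 4, 4))
        lat.set_voxel_mm((2.0, 2.0, 2.0))
        c = rng.normal(size=lat.coeff_shape())
        g = lat.evaluate_grad(c)
        u = lat.evaluate(c)
        interior = (slice(2, -2),) * 3
        for comp in range(3):
            for ax in range(3):
                # central differences carry O(h²) error against the exact
                # spline derivative; require agreement at the few-percent
                # level relative to the gradient's dynamic range
                # expected FD truncation ~ (voxel/knot)² ≈ 6% of the range here
                fd = np.gradient(u[..., comp], 2.0, axis=ax)
                err = np.abs(g[interior + (comp, ax)] - fd[interior]).max()
                assert err < 0.10 * np.abs(fd[interior]).max()


class TestWarp:
    def test_zero_field_is_identity(self, small_volume):
        fld = DisplacementField(np.zeros((*small_volume.shape, 3)),
                                small_volume.spacing_mm, small_volume.origin_mm)
        out = warp(small_volume, fld)
        assert np.allclose(out.data, small_volume.data)

    def test_one_voxel_shift_with_air_fill(self):
        data = np.arange(5 * 4 * 4, dtype=float).reshape(5, 4, 4)
        vol = ImageVolume(data=data, spacing_mm=(2, 2, 2))
        shift = np.zeros((5, 4, 4, 3))
        shift[..., 0] = 2.0  # one voxel along x
        out = warp(vol, DisplacementField(shift, (2, 2, 2))).data
        assert np.allclose(out[:-1], data[1:])
        assert np.allclose(out[-1], -1000.0)

    def test_geometry_mismatch_rejected(self, small_volume):
        fld = DisplacementField(np.zeros((3, 3, 3, 3)), small_volume.spacing_mm)
        with pytest.raises(Exception, match="mismatch"):
            warp(small_volume, fld)

    def test_truth_field_maps_inhale_back_to_exhale(self):
        # density rescaling off so intensities correspond between the phases
        p = generate_phantom(
            PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(2.5,) * 3,
                        noise_sd_hu=0.0, density_rescale=False, seed=9)
        )
        out = warp(p.inhale, p.truth_dvf)
        lung = p.truth_lungs.data > 0
        from scipy.ndimage import binary_erosion

        core = binary_erosion(lung, iterations=2)
        mad = np.abs(out.data - p.exhale.data)[core].mean()
        assert mad < 10.0  # interpolation-level residual, well below noise SD 20


class TestBendingEnergy:
    def test_zero_and_affine_fields_have_zero_energy(self):
        zero = DisplacementField(np.zeros((10, 10, 10, 3)), spacing_mm=(2, 2, 2))
        assert bending_energy(zero) == 0.0
        grid = ImageVolume(data=np.zeros((10, 10, 10)), spacing_mm=(2, 2, 2))
        aff = analytic_dvf("affine", {"A": np.diag([0.1, -0.05, 0.2]), "offset": (1, 2, 3)}, grid)
        assert bending_energy(aff.field) == pytest.approx(0.0, abs=1e-18)

    def test_matches_independent_summation_oracle(self):
        grid = ImageVolume(data=np.zeros((12, 12, 12)), spacing_mm=(2, 3, 4))
        fld = analytic_dvf("smooth_random", {"amplitude": 3.0, "seed": 7}, grid).field
        total = 0.0
        for i in range(3):
            for j in range(3):
                dj = np.gradient(fld.vectors[..., i], fld.spacing_mm[j], axis=j)
                for k in range(3):
                    djk = np.gradient(dj, fld.spacing_mm[k], axis=k)
                    total += np.sum(djk**2)
        total *= fld.voxel_volume_mm3
        assert bending_energy(fld) == pytest.approx(total, rel=1e-8)


class TestRegisterBspline:
    def test_self_registration_yields_null_field(self, coarse_pair):
        cfg = RegistrationConfig(
            pyramid_levels=1, control_spacing_mm=(32.0,), shrink_factors=(2,),
            smoothing_sigmas=(1.0,), max_iterations=(20,),
        )
        res = register_bspline(coarse_pair.exhale, coarse_pair.exhale, cfg)
        assert np.abs(res.dvf.vectors).max() < 0.1 * 4.0

    def test_known_translation_recovery(self, coarse_pair):
        vol = coarse_pair.exhale
        shift = np.zeros((*vol.shape, 3))
        shift[..., 0] = 4.0
        moving = warp(vol, DisplacementField(shift, vol.spacing_mm, vol.origin_mm))
        res = register_bspline(vol, moving, FAST)
        th = _Thorax(coarse_pair.spec)
        pts = _grid_points(th.shape, th.spacing, th.origin)
        body = th.body_radius(pts) <= 0.95
        # moving(x) = fixed(x + 4): registration recovers u = -4 mm along x
        assert res.dvf.vectors[..., 0][body].mean() == pytest.approx(-4.0, abs=0.5)
        assert abs(res.dvf.vectors[..., 1][body].mean()) < 0.5

    def test_deterministic_and_metric_monotone(self, coarse_pair):
        vol = coarse_pair.exhale
        shift = np.zeros((*vol.shape, 3))
        shift[..., 2] = 3.0
        moving = warp(vol, DisplacementField(shift, vol.spacing_mm, vol.origin_mm))
        r1 = register_bspline(vol, moving, FAST)
        r2 = register_bspline(vol, moving, FAST)
        assert np.array_equal(r1.dvf.vectors, r2.dvf.vectors)
        for hist in r1.metric_history:
            assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))
        assert r1.final_metric < r1.metric_history[0][0]

    def test_non_overlapping_fov_rejected(self, coarse_pair):
        far = ImageVolume(
            data=coarse_pair.exhale.data,
            spacing_mm=coarse_pair.exhale.spacing_mm,
            origin_mm=coarse_pair.exhale.origin_mm + 10_000.0,
        )
        with pytest.raises(RegistrationError, match="overlap"):
            register_bspline(coarse_pair.exhale, far)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RegistrationConfig(metric="mi")
        with pytest.raises(ValueError):
            RegistrationConfig(control_spacing_mm=(16.0, 32.0))  # must be coarse→fine
        with pytest.raises(ValueError):
            RegistrationConfig(bending_weight=-1.0)
        cfg = RegistrationConfig(control_spacing_mm=(4.0, 3.0))
        vol = ImageVolume(data=np.zeros((8, 8, 8)), spacing_mm=(2, 2, 2))
        with pytest.raises(ValueError, match="twice"):
            cfg.validate_against(vol)

    def test_config_json_round_trip(self):
        cfg = RegistrationConfig(metric="ncc", bending_weight=0.5)
        assert RegistrationConfig.from_json(cfg.to_json()) == cfg
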