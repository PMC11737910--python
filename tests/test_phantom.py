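import numpy as np
import pytest
from scipy import ndimage

from bhctvi import (
    FoldingError,
    ImageVolume,
    PhantomSpec,
    analytic_dvf,
    generate_phantom,
    jacobian_map,
)

GRID = ImageVolume(data=np.zeros((16, 16, 16)), spacing_mm=(2, 2, 2), origin_mm=(1, 1, 1))


class TestAnalyticFields:
    def test_affine_zero_matrix_gives_identity(self):
        out = analytic_dvf("affine", {"A": np.zeros((3, 3))}, GRID)
        assert np.all(out.field.vectors == 0.0)
        assert np.all(out.closed_form_jacobian(np.zeros((5, 3))) == 1.0)

    def test_affine_diagonal_stretch(self):
        A = np.diag([0.1, 0.0, 0.0])
        out = analytic_dvf("affine", {"A": A}, GRID)
        x = GRID.coords_mm()[0]
        assert np.allclose(out.field.vectors[..., 0], 0.1 * x[:, None, None])
        assert np.all(out.field.vectors[..., 1:] == 0.0)
        assert np.allclose(out.closed_form_jacobian(np.zeros((2, 3))), 1.1)

    def test_affine_singular_expansion_rejected(self):
        with pytest.raises(FoldingError):
            analytic_dvf("affine", {"A": -1.5 * np.eye(3)}, GRID)

    def test_gravity_gradient_closed_form_is_linear(self):
        out = analytic_dvf(
            "gravity_gradient",
            {"direction": (0, 1, 0), "slope": 0.005, "base": 0.1},
            GRID,
        )
        jac = jacobian_map(out.field).data
        pts = np.stack(np.meshgrid(*GRID.coords_mm(), indexing="ij"), axis=-1)
        expect = out.closed_form_jacobian(pts)
        interior = (slice(1, -1),) * 3
        assert np.allclose(jac[interior], expect[interior], atol=1e-9)

    def test_smooth_random_is_seeded_and_bounded(self):
        a = analytic_dvf("smooth_random", {"amplitude": 3.0, "seed": 7}, GRID)
        b = analytic_dvf("smooth_random", {"amplitude": 3.0, "seed": 7}, GRID)
        c = analytic_dvf("smooth_random", {"amplitude": 3.0, "seed": 8}, GRID)
        assert np.array_equal(a.field.vectors, b.field.vectors)
        assert not np.array_equal(a.field.vectors, c.field.vectors)
        assert np.abs(a.field.vectors).max() == pytest.approx(3.0)
        assert a.closed_form_jacobian is None


class TestGeneratePhantom:
    def test_no_breathing_case_is_bit_identical(self):
        p = generate_phantom(
            PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(2.5,) * 3,
                        global_expansion=1.0, gravity_gradient=0.0, noise_sd_hu=0.0)
        )
        assert np.array_equal(p.inhale.data, p.exhale.data)
        assert np.all(p.truth_dvf.vectors == 0.0)
        assert np.all(jacobian_map(p.truth_dvf).data == 1.0)

    def test_volume_ratio_matches_target_expansion(self):
        p = generate_phantom(
            PhantomSpec(grid_shape=(64, 64, 64), global_expansion=1.30,
                        gravity_gradient=0.0, noise_sd_hu=0.0)
        )
        n_ex = (p.truth_lungs.data > 0).sum()
        n_in = (p.truth_lungs_inhale.data > 0).sum()
        assert n_in / n_ex == pytest.approx(1.30, abs=0.02 * 1.30)

    def test_mean_truth_jacobian_hits_global_expansion(self, supine_pair):
        assert supine_pair.meta["mean_truth_jacobian_lung"] == pytest.approx(1.30, rel=0.02)

    def test_supine_dependent_half_expands_more(self, supine_pair):
        jac = jacobian_map(supine_pair.truth_dvf).data
        lung = supine_pair.truth_lungs.data > 0
        y = supine_pair.truth_lungs.origin_mm[1] + 2.5 * np.arange(48)
        dorsal = np.broadcast_to(y[None, :, None] >= 60.0, lung.shape)
        assert jac[lung & dorsal].mean() > jac[lung & ~dorsal].mean() + 0.05

    def test_determinism_bit_identical(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=(4,) * 3, seed=5)
        a, b = generate_phantom(spec), generate_phantom(spec)
        assert np.array_equal(a.exhale.data, b.exhale.data)
        assert np.array_equal(a.inhale.data, b.inhale.data)
        assert np.array_equal(a.truth_dvf.vectors, b.truth_dvf.vectors)

    def test_volume_consistency_integral_of_jacobian(self, quiet_pair):
        # ∫ J dV over the exhale lungs equals the inhale lung volume (within 2%)
        jac = jacobian_map(quiet_pair.truth_dvf).data
        lung = quiet_pair.truth_lungs.data > 0
        predicted = jac[lung].sum()
        actual = (quiet_pair.truth_lungs_inhale.data > 0).sum()
        assert predicted == pytest.approx(actual, rel=0.02)

    def test_supine_prone_jacobians_mirror_in_lung_interior(self):
        kw = dict(grid_shape=(48, 48, 48), spacing_mm=(2.5,) * 3, noise_sd_hu=0.0)
        ps = generate_phantom(PhantomSpec(position="supine", **kw))
        pp = generate_phantom(PhantomSpec(position="prone", **kw))
        js = jacobian_map(ps.truth_dvf).data
        jp = jacobian_map(pp.truth_dvf).data[:, ::-1, :]
        core = ndimage.binary_erosion(ps.truth_lungs.data > 0, iterations=2)
        assert np.abs(js - jp)[core].max() < 1e-12

    def test_single_lung_phantom(self):
        p = generate_phantom(
            PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(2.5,) * 3, lungs="right")
        )
        labels = np.unique(p.truth_lungs.data)
        assert set(labels) == {0, 2}
        assert p.meta["mean_truth_jacobian_lung"] == pytest.approx(1.30, rel=0.02)

    def test_extreme_deformation_is_rejected_as_folding(self):
        with pytest.raises(FoldingError):
            generate_phantom(
                PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(2.5,) * 3,
                            global_expansion=2.2, gravity_gradient=0.8)
            )

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(position="standing")
        with pytest.raises(ValueError):
            PhantomSpec(global_expansion=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(spacing_mm=(2.0, -1.0, 2.0))

    def test_spec_json_round_trip(self):
        spec = PhantomSpec(position="prone", seed=3, noise_sd_hu=5.0)
        assert PhantomSpec.from_json(spec.to_json()) == spec

    def test_save_writes_standard_files(self, tmp_path, quiet_pair):
        out = quiet_pair.save(tmp_path / "pair")
        for name in ("exhale.nii.gz", "inhale.nii.gz", "truth_dvf.nii.gz",
                     "truth_lungs.nii.gz", "phantom_spec.json"):
            assert (out / name).exists()
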