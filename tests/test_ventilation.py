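import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bhctvi import (
    DisplacementField,
    ImageVolume,
    analytic_dvf,
    functional_mask,
    jacobian_map,
    percentile_map,
)

GRID = ImageVolume(data=np.zeros((16, 16, 16)), spacing_mm=(2, 2, 2), origin_mm=(1, 1, 1))


def _fd_cofactor_jacobian(u, spacing, idx):
    """Independent oracle: assemble I + grad u entry by entry with the same
    finite-difference stencils and expand the determinant by cofactors."""
    i, j, k = idx
    A = np.empty((3, 3))
    for comp in range(3):
        for ax in range(3):
            lo = [i, j, k]
            hi = [i, j, k]
            n = u.shape[ax]
            pos = idx[ax]
            if pos == 0:
                hi[ax] += 1
                d = (u[tuple(hi) + (comp,)] - u[tuple(lo) + (comp,)]) / spacing[ax]
            elif pos == n - 1:
                lo[ax] -= 1
                d = (u[tuple(hi) + (comp,)] - u[tuple(lo) + (comp,)]) / spacing[ax]
            else:
                lo[ax] -= 1
                hi[ax] += 1
                d = (u[tuple(hi) + (comp,)] - u[tuple(lo) + (comp,)]) / (2 * spacing[ax])
            A[comp, ax] = d
    A += np.eye(3)
    return (
        A[0, 0] * (A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1])
        - A[0, 1] * (A[1, 0] * A[2, 2] - A[1, 2] * A[2, 0])
        + A[0, 2] * (A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0])
    )


class TestJacobianMap:
    def test_zero_field_gives_exactly_one(self):
        fld = DisplacementField(np.zeros((16, 16, 16, 3)), spacing_mm=(2, 2, 2))
        jac = jacobian_map(fld)
        assert np.all(jac.data == 1.0)

    def test_affine_stretch_matches_analytic_determinant(self):
        out = analytic_dvf("affine", {"A": np.diag([0.1, 0.2, 0.0])}, GRID)
        jac = jacobian_map(out.field).data
        interior = (slice(1, -1),) * 3
        assert np.allclose(jac[interior], 1.1 * 1.2 * 1.0, atol=1e-12)

    def test_matches_cofactor_expansion_oracle_on_random_voxels(self):
        out = analytic_dvf("smooth_random", {"amplitude": 3.0, "seed": 7}, GRID)
        jac = jacobian_map(out.field).data
        rng = np.random.default_rng(0)
        spacing = out.field.spacing_mm
        for _ in range(20):
            idx = tuple(rng.integers(1, 15, size=3))
            assert jac[idx] == pytest.approx(
                _fd_cofactor_jacobian(out.field.vectors, spacing, idx), abs=1e-10
            )

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            jacobian_map(DisplacementField(np.zeros((2, 8, 8, 3))))

    def test_mirror_equivariance(self):
        out = analytic_dvf("smooth_random", {"amplitude": 2.0, "seed": 3}, GRID)
        jac = jacobian_map(out.field).data
        for axis in range(3):
            flipped = np.flip(out.field.vectors, axis=axis).copy()
            flipped[..., axis] *= -1.0
            jac_flip = jacobian_map(
                DisplacementField(flipped, out.field.spacing_mm, out.field.origin_mm)
            ).data
            assert np.allclose(np.flip(jac_flip, axis=axis), jac, atol=1e-12)


class TestPercentiles:
    def _vol(self, values):
        data = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        return ImageVolume(data=data), np.ones_like(data, dtype=bool)

    def test_constant_values_rank_fifty(self):
        jac, mask = self._vol([2.0] * 8)
        ranks = percentile_map(jac, mask).data
        assert np.all(ranks == 50.0)

    def test_midrank_formula_four_values(self):
        jac, mask = self._vol([1.0, 1.1, 1.2, 1.3])
        ranks = percentile_map(jac, mask).data.ravel()
        assert np.allclose(ranks, [12.5, 37.5, 62.5, 87.5])

    def test_out_of_mask_is_nan_and_empty_mask_rejected(self):
        jac, mask = self._vol([1.0, 2.0, 3.0])
        mask[0] = False
        ranks = percentile_map(jac, mask).data
        assert np.isnan(ranks[0, 0, 0]) and not np.isnan(ranks[1:, 0, 0]).any()
        with pytest.raises(ValueError, match="empty"):
            percentile_map(jac, np.zeros_like(mask))

    @given(st.lists(st.integers(-500, 500), min_size=3, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_ranks_invariant_under_monotone_transform(self, cents):
        # coarse value grid so the monotone transform cannot collapse
        # distinct floats into ties through rounding
        values = [c / 100.0 for c in cents]
        jac, mask = self._vol(values)
        r1 = percentile_map(jac, mask).data
        jac2 = ImageVolume(data=3.0 * jac.data + 7.0)  # strictly monotone
        r2 = percentile_map(jac2, mask).data
        assert np.allclose(r1, r2)


class TestFunctionalMask:
    def test_top_quartile_of_distinct_values(self):
        rng = np.random.default_rng(1)
        values = rng.permutation(1000).astype(float)
        jac = ImageVolume(data=values.reshape(10, 10, 10))
        mask = np.ones((10, 10, 10), dtype=bool)
        hf = functional_mask(percentile_map(jac, mask), 75.0)
        assert hf.sum() == 250

    def test_constant_map_flags_nothing(self):
        jac = ImageVolume(data=np.ones((5, 5, 5)))
        hf = functional_mask(percentile_map(jac, np.ones((5, 5, 5), bool)), 75.0)
        assert hf.sum() == 0

    def test_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        jac = ImageVolume(data=rng.normal(size=(8, 8, 8)))
        pmap = percentile_map(jac, np.ones((8, 8, 8), bool))
        counts = [functional_mask(pmap, t).sum() for t in (5, 25, 50, 75, 95)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_threshold_domain(self):
        pmap = percentile_map(ImageVolume(data=np.ones((3, 3, 3))), np.ones((3, 3, 3), bool))
        for bad in (0.0, 100.0, -1.0):
            with pytest.raises(ValueError):
                functional_mask(pmap, bad)


def test_volume_conservation_on_phantom(quiet_pair):
    """Σ V × voxel volume over the exhale lungs = inhale lung volume (2%)."""
    jac = jacobian_map(quiet_pair.truth_dvf)
    lung = quiet_pair.truth_lungs.data > 0
    vox = quiet_pair.exhale.voxel_volume_mm3
    predicted_ml = jac.data[lung].sum() * vox / 1000.0
    actual_ml = (quiet_pair.truth_lungs_inhale.data > 0).sum() * vox / 1000.0
    assert predicted_ml == pytest.approx(actual_ml, rel=0.02)
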