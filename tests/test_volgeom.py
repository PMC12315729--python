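import numpy as np
import pytest

from omtemplate.volgeom import (
    AffineTransform,
    DisplacementField,
    GridMismatchError,
    ImageGrid,
    ScalarImage,
    TensorImage,
    compose_affine_warp,
    compose_warps,
    components_to_matrices,
    fa_from_eigenvalues,
    fa_map,
    invert_warp,
    jacobian_determinant_map,
    log_euclidean_mean,
    matrices_to_components,
    mean_warp,
    resample_scalar,
    resample_tensor,
    voxelwise_mean_valid,
    voxelwise_median,
)

from conftest import smooth_random_field, smooth_random_image


def translation_field(grid, t):
    disp = np.zeros(grid.shape + (3,))
    disp[...] = t
    return DisplacementField(grid, disp)


class TestTypes:
    def test_grid_requires_invertible_affine(self):
        with pytest.raises(ValueError):
            ImageGrid((4, 4, 4), np.zeros((4, 4)))

    def test_grid_voxel_sizes(self, grid8):
        assert np.allclose(grid8.voxel_sizes, 2.0)
        assert grid8.voxel_volume == pytest.approx(8.0)

    def test_scalar_rejects_nonfinite(self, grid8):
        vals = np.zeros(grid8.shape)
        vals[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            ScalarImage(grid8, vals)

    def test_rigid_tag_checks_orthogonality(self):
        mat = np.eye(4)
        mat[0, 0] = 2.0
        with pytest.raises(ValueError):
            AffineTransform(mat, "rigid6")

    def test_tensor_validity_flags_nonpositive(self, grid8):
        comp = np.zeros(grid8.shape + (6,))
        comp[0, 0, 0] = [1, 0, 0, 1, 0, 1]       # identity: valid
        comp[1, 0, 0] = [1, 0, 0, 1, 0, -1.0]    # negative eigenvalue
        timg = TensorImage(grid8, comp)
        assert timg.valid[0, 0, 0]
        assert not timg.valid[1, 0, 0]
        assert not timg.valid[2, 0, 0]  # zero tensor

    def test_component_matrix_round_trip(self):
        rng = np.random.default_rng(0)
        comp = rng.normal(size=(5, 6))
        assert np.allclose(matrices_to_components(components_to_matrices(comp)), comp)


class TestComposeWarps:
    def test_identity_outer_leaves_inner(self, grid8):
        w = smooth_random_field(grid8, 1.5, 1.5, seed=1)
        out = compose_warps(DisplacementField.zero(grid8), w)
        assert np.allclose(out.disp, w.disp)

    def test_translations_add(self, grid8):
        t1, t2 = np.array([1.0, -2.0, 0.5]), np.array([0.25, 1.0, -1.0])
        out = compose_warps(translation_field(grid8, t1),
                            translation_field(grid8, t2))
        assert np.allclose(out.disp, t1 + t2)

    def test_inverse_composition_residual(self):
        # derived oracle: residual of w^-1 o w measured directly on the grid;
        # the field must be smooth everywhere (wide smooth envelope) for the
        # trilinear interpolation error to stay below the 0.05-voxel bound
        from scipy import ndimage

        rng = np.random.default_rng(3)
        grid = ImageGrid.isotropic((32, 32, 32), 2.0)
        disp = rng.standard_normal(grid.shape + (3,))
        for c in range(3):
            disp[..., c] = ndimage.gaussian_filter(disp[..., c], 5.0)
        for ax, n in enumerate(grid.shape):
            t = np.clip(np.minimum(np.arange(n), np.arange(n)[::-1]) / 10.0, 0, 1)
            ramp = t * t * (3 - 2 * t)
            shape = [1, 1, 1, 1]
            shape[ax] = n
            disp *= ramp.reshape(shape)
        disp *= 2.0 / np.linalg.norm(disp, axis=-1).max()
        w = DisplacementField(grid, disp)
        w_inv = invert_warp(w, tol=0.01)
        comp = compose_warps(w_inv, w)
        vox = np.max(np.linalg.norm(comp.disp, axis=-1)) / 2.0  # voxel = 2 mm
        assert vox <= 0.05

    def test_oob_count(self, grid8):
        w = translation_field(grid8, np.array([100.0, 0, 0]))
        _, oob = compose_warps(translation_field(grid8, np.zeros(3)), w,
                               return_oob_count=True)
        assert oob == 8 ** 3


class TestComposeAffineWarp:
    def test_identity_affine(self, grid8):
        w = smooth_random_field(grid8, 1.0, 1.5, seed=2)
        out = compose_affine_warp(AffineTransform.identity(), w)
        assert np.allclose(out.disp, w.disp)

    def test_translation_on_zero_warp(self, grid8):
        t = np.array([3.0, -1.0, 2.0])
        out = compose_affine_warp(AffineTransform.translation_mm(t),
                                  DisplacementField.zero(grid8))
        assert np.allclose(out.disp, t)

    def test_scaling_displacement_is_exact(self):
        grid = ImageGrid.isotropic((2, 3, 4), 1.0, origin=(1.0, 2.0, 3.0))
        mat = np.diag([2.0, 2.0, 2.0, 1.0])
        out = compose_affine_warp(AffineTransform(mat),
                                  DisplacementField.zero(grid))
        assert np.allclose(out.disp[0, 0, 0], [1.0, 2.0, 3.0])


class TestInvertWarp:
    def test_uniform_translation(self, grid8):
        t = np.array([1.0, 0.5, -0.5])
        inv = invert_warp(translation_field(grid8, t))
        assert np.allclose(inv.disp, -t, atol=1e-6)

    def test_zero_field(self, grid8):
        inv = invert_warp(DisplacementField.zero(grid8))
        assert np.allclose(inv.disp, 0.0)

    def test_sinusoidal_residual(self):
        grid = ImageGrid.isotropic((24, 24, 24), 1.0)
        x = grid.world_coords()
        disp = np.zeros(grid.shape + (3,))
        disp[..., 0] = 2.0 * np.sin(2 * np.pi * x[1] / 24.0)  # max 2 voxels
        w = DisplacementField(grid, disp)
        inv = invert_warp(w, tol=0.01)
        comp = compose_warps(w, inv)
        resid = np.linalg.norm(comp.disp, axis=-1)
        interior = resid[2:-2, 2:-2, 2:-2]
        assert np.mean(interior <= 0.01) >= 0.99


class TestMeanWarp:
    def test_symmetric_pair_cancels(self, grid8):
        w = smooth_random_field(grid8, 1.0, 1.5, seed=4)
        neg = DisplacementField(grid8, -w.disp)
        assert np.allclose(mean_warp([w, neg]).disp, 0.0)

    def test_identical_fields(self, grid8):
        w = smooth_random_field(grid8, 1.0, 1.5, seed=5)
        assert np.allclose(mean_warp([w, w, w]).disp, w.disp)

    def test_translations_average(self, grid8):
        w1 = translation_field(grid8, np.array([1.0, 0, 0]))
        w2 = translation_field(grid8, np.array([3.0, 0, 0]))
        assert np.allclose(mean_warp([w1, w2]).disp, [2.0, 0, 0])

    def test_permutation_invariance(self, grid8):
        # float summation order varies with permutation; equality holds to
        # a few ulps
        ws = [smooth_random_field(grid8, 1.0, 1.5, seed=s) for s in range(4)]
        a = mean_warp(ws).disp
        b = mean_warp(ws[::-1]).disp
        assert np.allclose(a, b, rtol=0, atol=1e-14)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            mean_warp([])

    def test_grid_mismatch(self, grid8, grid16):
        with pytest.raises(GridMismatchError):
            mean_warp([DisplacementField.zero(grid8),
                       DisplacementField.zero(grid16)])


class TestJacobian:
    def test_zero_field_gives_one(self, grid8):
        jac = jacobian_determinant_map(DisplacementField.zero(grid8))
        assert np.allclose(jac.values, 1.0)

    def test_uniform_scaling(self, grid8):
        x = grid8.world_coords()
        disp = np.moveaxis(0.1 * x, 0, -1)  # phi(x) = 1.1 x
        jac = jacobian_determinant_map(DisplacementField(grid8, disp))
        assert np.allclose(jac.values, 1.1 ** 3, atol=1e-10)

    def test_linear_map_matches_closed_form(self, grid8):
        # derived oracle: det of the generating linear part
        L = np.array([[1.05, 0.02, 0.0], [0.01, 0.97, 0.03], [0.0, 0.02, 1.1]])
        x = grid8.world_coords().reshape(3, -1)
        disp = (L @ x - x).T.reshape(grid8.shape + (3,))
        jac = jacobian_determinant_map(DisplacementField(grid8, disp))
        assert np.allclose(jac.values[1:-1, 1:-1, 1:-1], np.linalg.det(L),
                           atol=1e-6)

    def test_chain_rule_property(self, grid16):
        from omtemplate.volgeom import sample_displacement

        outer = smooth_random_field(grid16, 1.5, 3.0, seed=6)
        inner = smooth_random_field(grid16, 1.5, 3.0, seed=7)
        composed = compose_warps(outer, inner)
        j_comp = jacobian_determinant_map(composed).values
        j_inner = jacobian_determinant_map(inner).values
        # outer Jacobian sampled at inner-mapped points (brute force)
        j_outer = jacobian_determinant_map(outer).values
        from scipy import ndimage
        vox = outer.grid.world_to_voxel_coords(inner.positions()).reshape(3, -1)
        j_outer_at = ndimage.map_coordinates(j_outer, vox, order=1,
                                             mode="nearest")
        expected = j_outer_at.reshape(grid16.shape) * j_inner
        sl = (slice(3, -3),) * 3
        rel = np.abs(j_comp[sl] - expected[sl]) / np.abs(expected[sl])
        assert np.percentile(rel, 95) < 0.02


class TestResampleScalar:
    def test_identity_map_orders_0_1(self, grid8):
        img = smooth_random_image(grid8, 8)
        for order in (0, 1):
            out = resample_scalar(img, DisplacementField.zero(grid8), order=order)
            assert np.allclose(out.values, img.values)

    def test_integer_translation_shifts(self, grid8):
        img = smooth_random_image(grid8, 9)
        t = translation_field(grid8, np.array([2.0, 0, 0]))  # +1 voxel
        out = resample_scalar(img, t, order=1)
        assert np.allclose(out.values[:-1], img.values[1:])
        assert np.allclose(out.values[-1], 0.0)

    def test_halfvoxel_round_trip(self):
        # smooth phantom (Gaussian blob, effectively zero at the boundary)
        grid = ImageGrid.isotropic((24, 24, 24), 1.0)
        x = grid.world_coords()
        r2 = sum((x[i] - 11.5) ** 2 for i in range(3))
        img = ScalarImage(grid, np.exp(-r2 / (2 * 2.5 ** 2)))
        fwd = resample_scalar(img, translation_field(grid, np.array([0.5, 0, 0])),
                              order=3)
        back = resample_scalar(fwd, translation_field(grid, np.array([-0.5, 0, 0])),
                               order=3)
        assert np.max(np.abs(back.values - img.values)) <= 1e-3

    def test_invalid_order(self, grid8):
        img = smooth_random_image(grid8, 11)
        with pytest.raises(ValueError):
            resample_scalar(img, DisplacementField.zero(grid8), order=7)


def _uniform_tensor_image(grid, mat):
    comp = np.tile(matrices_to_components(mat), grid.shape + (1,))
    return TensorImage(grid, comp)


class TestResampleTensor:
    def test_identity_map(self, grid8):
        D = np.diag([3e-3, 1e-3, 1e-3])
        timg = _uniform_tensor_image(grid8, D)
        out = resample_tensor(timg, DisplacementField.zero(grid8))
        assert np.allclose(out.components[out.valid],
                           timg.components[out.valid], atol=1e-12)

    def test_rotation_equivariance(self):
        # map phi(x) = R^T x about the grid center => anatomy rotates by R
        grid = ImageGrid.isotropic((12, 12, 12), 1.0, origin=(-5.5, -5.5, -5.5))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        D = np.diag([3e-3, 1e-3, 0.5e-3])
        timg = _uniform_tensor_image(grid, D)
        mat4 = np.eye(4)
        mat4[:3, :3] = R.T
        out = resample_tensor(timg, AffineTransform(mat4, "rigid6"), out_grid=grid)
        expected = R @ D @ R.T
        got = components_to_matrices(out.components[6, 6, 6])
        assert np.allclose(got, expected, atol=1e-6)
        evals = np.linalg.eigvalsh(got)
        assert np.allclose(np.sort(evals), np.sort(np.diag(D)), atol=1e-6)
        # principal axis moved from x to y
        v = np.linalg.eigh(got)[1][:, -1]
        assert abs(v[1]) > 0.999

    def test_pure_translation_preserves_orientation(self, grid8):
        D = np.diag([3e-3, 1e-3, 1e-3])
        timg = _uniform_tensor_image(grid8, D)
        out = resample_tensor(timg, translation_field(grid8, np.array([2.0, 0, 0])))
        inner = out.components[2:-2, 2:-2, 2:-2]
        assert np.allclose(inner, matrices_to_components(D), atol=1e-12)

    def test_invalid_propagates(self, grid8):
        comp = np.tile(matrices_to_components(np.eye(3) * 1e-3),
                       grid8.shape + (1,))
        comp[4, 4, 4] = 0.0
        timg = TensorImage(grid8, comp)
        out = resample_tensor(timg, DisplacementField.zero(grid8))
        assert not out.valid[4, 4, 4]


class TestLogEuclideanMean:
    def test_identical_tensors(self):
        D = np.diag([3e-3, 1e-3, 0.5e-3])
        mean, ok = log_euclidean_mean(np.stack([D, D, D]))
        assert ok
        assert np.allclose(mean, D, atol=1e-12)

    def test_diagonal_geometric_mean(self):
        a = np.diag([4.0, 2.0, 1.0])
        b = np.diag([1.0, 8.0, 9.0])
        mean, _ = log_euclidean_mean(np.stack([a, b]))
        assert np.allclose(np.diag(mean), np.sqrt(np.diag(a) * np.diag(b)))
        assert np.allclose(mean, np.diag(np.diag(mean)), atol=1e-12)

    def test_anti_swelling_vs_euclidean(self):
        # the Euclidean mean of diag(4,1,1) and diag(1,1,4) swells: its
        # determinant (6.25) exceeds the inputs' (4); the log-Euclidean mean
        # keeps the geometric-mean determinant exactly
        a = np.diag([4.0, 1.0, 1.0])
        b = np.diag([1.0, 1.0, 4.0])
        le, _ = log_euclidean_mean(np.stack([a, b]))
        eu = (a + b) / 2.0
        assert np.linalg.det(le) == pytest.approx(4.0)
        assert np.linalg.det(eu) > np.linalg.det(le)

    def test_validity_excludes_invalid(self):
        good = np.diag([2.0, 1.0, 1.0])
        bad = np.zeros((3, 3))
        mean, ok = log_euclidean_mean(np.stack([good, bad]))
        assert ok
        assert np.allclose(mean, good)

    def test_no_valid_gives_zero(self):
        mean, ok = log_euclidean_mean(np.zeros((2, 3, 3)))
        assert not ok
        assert np.allclose(mean, 0.0)

    def test_anti_swelling_property_1000_pairs(self):
        # property: the log-Euclidean mean never swells the determinant —
        # det(LE mean) is the geometric mean of the input determinants and
        # the Euclidean mean's determinant is always at least as large
        # (Minkowski determinant inequality).  NOTE: the analogous statement
        # for FA is false (counter-example: diag(4,1,1) vs diag(1,1,4)).
        rng = np.random.default_rng(42)
        n = 1000
        evals = rng.uniform(0.2, 3.0, size=(2, n, 3))
        evals[..., 0] += 2.0  # guarantee anisotropy
        mats = []
        for k in range(2):
            q, _ = np.linalg.qr(rng.normal(size=(n, 3, 3)))
            mats.append(np.einsum("nij,nj,nkj->nik", q, evals[k], q))
        pair = np.stack(mats)  # (2, n, 3, 3)
        le, _ = log_euclidean_mean(pair)
        eu = pair.mean(axis=0)
        det_le = np.linalg.det(le)
        det_eu = np.linalg.det(eu)
        det_geo = np.sqrt(np.linalg.det(pair[0]) * np.linalg.det(pair[1]))
        assert np.allclose(det_le, det_geo, rtol=1e-8)
        assert np.all(det_eu >= det_le * (1 - 1e-12))


class TestFA:
    def test_isotropic_zero(self, grid8):
        timg = _uniform_tensor_image(grid8, np.eye(3) * 2e-3)
        assert np.allclose(fa_map(timg).values, 0.0, atol=1e-12)

    def test_maximal_anisotropy(self):
        fa = fa_from_eigenvalues(np.array([5.0, 0.0, 0.0]))
        assert fa == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        evals = np.array([3.0, 1.0, 1.0]) * 1e-3
        m = evals.mean()
        expected = np.sqrt(1.5 * np.sum((evals - m) ** 2) / np.sum(evals ** 2))
        assert fa_from_eigenvalues(evals) == pytest.approx(expected, abs=1e-12)

    def test_invalid_voxels_zero(self, grid8):
        comp = np.tile(matrices_to_components(np.diag([3e-3, 1e-3, 1e-3])),
                       grid8.shape + (1,))
        comp[0, 0, 0] = 0.0
        fa = fa_map(TensorImage(grid8, comp))
        assert fa.values[0, 0, 0] == 0.0
        assert fa.values[4, 4, 4] > 0.5


class TestVoxelwiseStats:
    def test_median_of_three(self, grid8):
        imgs = [ScalarImage(grid8, np.full(grid8.shape, v)) for v in (1, 2, 100)]
        assert np.allclose(voxelwise_median(imgs).values, 2.0)

    def test_median_of_identical(self, grid8):
        img = smooth_random_image(grid8, 12)
        assert np.allclose(voxelwise_median([img, img, img]).values, img.values)

    def test_mean_valid_ignores_invalid(self, grid8):
        a = ScalarImage(grid8, np.full(grid8.shape, 10.0))
        b = ScalarImage(grid8, np.full(grid8.shape, 99.0))
        va = np.ones(grid8.shape, dtype=bool)
        vb = np.zeros(grid8.shape, dtype=bool)
        out = voxelwise_mean_valid([a, b], [va, vb])
        assert np.allclose(out.values, 10.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            voxelwise_median([])
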