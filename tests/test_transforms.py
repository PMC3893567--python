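"""Parametric transforms: mapping, sparse Jacobians, averaging, inversion."""

import numpy as np
import pytest

from voxelreg.errors import ContractError, NonConvergenceError
from voxelreg.image import Geometry
from voxelreg.transforms import (AffineTransform, BSplineTransform,
                                 CompositeTransform, RigidTransform,
                                 SimilarityTransform, Transform,
                                 TranslationTransform, average_transforms,
                                 bspline_grid_for, displacement_field,
                                 invert_transform, read_transform,
                                 sparse_gradient_product, write_transform)


@pytest.fixture
def bspline3d(rng):
    grid = bspline_grid_for((0, 0, 0), (10, 10, 10), 3.0)
    return BSplineTransform(grid, rng.normal(0, 0.5, (3,) + tuple(grid.shape)))


@pytest.fixture
def bspline2d(rng):
    grid = bspline_grid_for((0, 0), (30, 30), 8.0)
    return BSplineTransform(grid, rng.normal(0, 1.0, (2,) + tuple(grid.shape)))


class TestMapping:
    def test_zero_coefficient_bspline_is_identity(self):
        grid = bspline_grid_for((0, 0, 0), (10, 10, 10), 2.0)
        t = BSplineTransform(grid)
        pts = np.random.default_rng(0).uniform(0, 10, (30, 3))
        assert np.allclose(t.map_points(pts), pts)

    def test_translation_moves_origin(self):
        t = TranslationTransform((1, 2, 3))
        assert np.allclose(t.map_point((0, 0, 0)), (1, 2, 3))

    def test_composite_equals_sequential_application(self, rng):
        members = [TranslationTransform((1, 0, 0)),
                   AffineTransform(3, 2 * np.eye(3))]
        comp = CompositeTransform(members)
        assert np.allclose(comp.map_point((0, 0, 0)), (2, 0, 0))
        pts = rng.uniform(-5, 5, (40, 3))
        expected = pts
        for m in members:
            expected = m.map_points(expected)
        assert np.array_equal(comp.map_points(pts), expected)  # bit-exact fold

    def test_rigid_rotation_preserves_distances(self, rng):
        t = RigidTransform(3, angles=(0.2, -0.4, 0.7), translation=(1, 2, 3),
                           center=(5, 5, 5))
        pts = rng.uniform(0, 10, (20, 3))
        mapped = t.map_points(pts)
        d0 = np.linalg.norm(pts[:10] - pts[10:], axis=1)
        d1 = np.linalg.norm(mapped[:10] - mapped[10:], axis=1)
        assert np.allclose(d0, d1)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ContractError):
            TranslationTransform((1, 2, 3)).map_point((0, 0))


class TestParameterJacobian:
    def test_bspline_support_size(self, bspline3d):
        jac = bspline3d.parameter_jacobian((5.0, 5.0, 5.0))
        assert jac.P == 64  # (3+1)^3
        assert jac.block_size == bspline3d.grid_size

    def test_partition_of_unity_at_interior_points(self, bspline3d, rng):
        pts = rng.uniform(0.5, 9.5, (100, 3))
        w, idx, inside = bspline3d.parameter_weights(pts)
        assert inside.all()
        assert np.abs(w.sum(axis=1) - 1.0).max() < 1e-10

    def test_translation_jacobian_is_identity(self):
        jac = TranslationTransform((0.0, 0.0)).parameter_jacobian((3.0, 4.0))
        assert np.array_equal(jac.to_dense(), np.eye(2))

    @pytest.mark.parametrize("make", [
        lambda: TranslationTransform((0.5, -1.0, 2.0)),
        lambda: RigidTransform(3, angles=(0.1, 0.2, -0.3),
                               translation=(1, 0, 2), center=(2, 2, 2)),
        lambda: SimilarityTransform(3, angles=(0.1, -0.2, 0.3), scale=1.1,
                                    translation=(0, 1, 0), center=(2, 2, 2)),
        lambda: AffineTransform(3, np.eye(3) + 0.1, offset=(1, 2, 3),
                                center=(1, 1, 1)),
    ], ids=["translation", "rigid", "similarity", "affine"])
    def test_dense_jacobians_match_finite_differences(self, make, rng):
        t = make()
        for p in rng.uniform(0, 6, (3, 3)):
            dense = t.parameter_jacobian(p).to_dense()
            fd = _fd_parameter_jacobian(t, p)
            assert np.abs(dense - fd).max() < 1e-6

    def test_sparse_bspline_jacobian_matches_brute_force(self, bspline3d):
        p = np.array([5.0, 4.0, 6.0])
        dense = bspline3d.parameter_jacobian(p).to_dense()
        cols = np.flatnonzero(np.abs(dense).sum(axis=0))
        fd = _fd_parameter_jacobian(bspline3d, p, cols)
        assert np.abs(dense[:, cols] - fd[:, cols]).max() < 1e-8

    def test_sparse_gradient_product_equals_dense(self, bspline3d, rng):
        p = np.array([5.0, 4.0, 6.0])
        jac = bspline3d.parameter_jacobian(p)
        g = rng.normal(size=3)
        sparse = sparse_gradient_product(jac, g)
        dense = jac.to_dense().T @ g
        assert np.abs(sparse.to_dense() - dense).max() < 1e-12

    def test_zero_gradient_gives_zero_product(self, bspline3d):
        jac = bspline3d.parameter_jacobian((5.0, 5.0, 5.0))
        out = sparse_gradient_product(jac, np.zeros(3))
        assert not out.values.any()

    def test_translation_gradient_product_returns_gradient(self):
        jac = TranslationTransform((0, 0, 0)).parameter_jacobian((1, 2, 3))
        g = np.array([0.3, -0.7, 1.1])
        assert np.allclose(sparse_gradient_product(jac, g).to_dense(), g)

    def test_outside_support_gives_empty_jacobian(self, bspline3d):
        jac = bspline3d.parameter_jacobian((1e4, 1e4, 1e4))
        assert jac.P == 0


class TestSpatialJacobian:
    def test_identity_determinant_is_one(self):
        t = TranslationTransform((1, 2, 3))
        assert t.spatial_jacobian_determinant((0, 0, 0)) == pytest.approx(1.0)

    def test_isotropic_scaling_determinant(self):
        t = AffineTransform(3, 1.5 * np.eye(3))
        assert t.spatial_jacobian_determinant((2, 2, 2)) == pytest.approx(1.5 ** 3)

    def test_bspline_matches_finite_differences(self, bspline3d):
        p = np.array([5.0, 5.0, 5.0])
        analytic = bspline3d.spatial_jacobian(p)
        fd = Transform.spatial_jacobian_batch(bspline3d, p[None, :], h=1e-4)[0]
        assert np.abs(analytic - fd).max() < 1e-6

    def test_composite_chain_rule(self, bspline3d):
        aff = AffineTransform(3, np.eye(3) * 0.9, offset=(1, 0, 0))
        comp = CompositeTransform([aff, bspline3d])
        p = np.array([5.0, 5.0, 5.0])
        fd = Transform.spatial_jacobian_batch(comp, p[None, :], h=1e-4)[0]
        assert np.abs(comp.spatial_jacobian(p) - fd).max() < 1e-5


class TestAveraging:
    def test_identity_members_average_to_identity(self):
        g = Geometry((6, 6, 6))
        u = average_transforms([TranslationTransform((0, 0, 0))] * 3, g)
        assert np.abs(u.field).max() == 0.0

    def test_two_translations_average_exactly(self):
        g = Geometry((6, 6))
        u = average_transforms([TranslationTransform((1, 0)),
                                TranslationTransform((3, 0))], g)
        assert np.allclose(u.field[..., 0], 2.0)
        assert np.allclose(u.field[..., 1], 0.0)

    def test_included_identity_counts_as_member(self):
        g = Geometry((5, 5))
        u = average_transforms([TranslationTransform((2, 0))], g,
                               include_identity=True)
        assert np.allclose(u.field[..., 0], 1.0)

    def test_singleton_average_reproduces_member_on_grid(self, bspline2d):
        g = Geometry((8, 8), (4.0, 4.0))
        u = average_transforms([bspline2d], g)
        pts = g.grid_points()
        assert np.abs(u.map_points(pts) - bspline2d.map_points(pts)).max() < 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ContractError):
            average_transforms([], Geometry((4, 4)))


class TestInversion:
    def test_translation_inverts_exactly(self):
        g = Geometry((6, 6, 6))
        v = invert_transform(TranslationTransform((1.5, -0.5, 2.0)), g)
        assert v.max_residual == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(v.map_point((3, 3, 3)), (1.5, 3.5, 1.0))

    def test_affine_matches_closed_form_inverse(self):
        g = Geometry((8, 8), (1.0, 1.0), (0.0, 0.0))
        a = AffineTransform(2, np.array([[1.05, 0.02], [-0.03, 0.97]]),
                            offset=(0.4, -0.2), center=(3.5, 3.5))
        v = invert_transform(a, g, tolerance=1e-10, max_iter=200)
        exact = a.inverse()
        pts = g.grid_points()
        assert np.abs(v.map_points(pts) - exact.map_points(pts)).max() < 1e-8

    def test_small_bspline_round_trip_residual(self, rng):
        grid = bspline_grid_for((0, 0, 0), (20, 20, 20), 5.0)
        t = BSplineTransform(grid, rng.normal(0, 0.3, (3,) + tuple(grid.shape)))
        g = Geometry((11, 11, 11), (2.0, 2.0, 2.0))
        v = invert_transform(t, g, tolerance=1e-3, max_iter=100)
        pts = g.grid_points()
        residual = np.linalg.norm(t.map_points(v.map_points(pts)) - pts, axis=1)
        assert residual.max() <= 1e-3

    def test_nonconvergence_reports_residual_and_location(self):
        # a contraction-violating map: strong expansion cannot be inverted
        g = Geometry((5, 5))
        bad = AffineTransform(2, -3.0 * np.eye(2))
        with pytest.raises(NonConvergenceError) as exc:
            invert_transform(bad, g, tolerance=1e-6, max_iter=5)
        assert exc.value.residual > 0
        assert exc.value.location is not None


class TestSerialization:
    @pytest.mark.parametrize("make", [
        lambda: TranslationTransform((0.5, -1.0)),
        lambda: SimilarityTransform(2, angles=0.3, translation=(1, 2),
                                    scale=1.05, center=(4, 4)),
        lambda: AffineTransform(3, np.eye(3) + 0.05, offset=(1, 0, 0)),
    ], ids=["translation", "similarity", "affine"])
    def test_parameter_file_round_trip(self, tmp_path, make, rng):
        t = make()
        write_transform(t, tmp_path / "t.txt")
        back = read_transform(tmp_path / "t.txt")
        pts = rng.uniform(0, 8, (10, t.dimension))
        assert np.allclose(back.map_points(pts), t.map_points(pts), atol=1e-12)

    def test_composite_with_bspline_round_trip(self, tmp_path, bspline2d, rng):
        comp = CompositeTransform([TranslationTransform((1.0, 0.0)), bspline2d])
        write_transform(comp, tmp_path / "c.txt")
        back = read_transform(tmp_path / "c.txt")
        pts = rng.uniform(0, 30, (20, 2))
        assert np.allclose(back.map_points(pts), comp.map_points(pts), atol=1e-12)

    def test_displacement_field_round_trip(self, tmp_path, bspline2d, rng):
        g = Geometry((9, 9), (4.0, 4.0))
        u = average_transforms([bspline2d], g)
        write_transform(u, tmp_path / "u.txt")
        back = read_transform(tmp_path / "u.txt")
        pts = rng.uniform(0, 30, (20, 2))
        assert np.allclose(back.map_points(pts), u.map_points(pts), atol=1e-6)


def test_displacement_field_materialization(bspline2d):
    g = Geometry((6, 6), (5.0, 5.0))
    field = displacement_field(bspline2d, g)
    pts = g.grid_points()
    expected = (bspline2d.map_points(pts) - pts).reshape(6, 6, 2)
    assert np.array_equal(field, expected)


def _fd_parameter_jacobian(t, point, cols=None, h=1e-6):
    mu0 = t.get_parameters()
    n = mu0.size
    cols = range(n) if cols is None else cols
    out = np.zeros((t.dimension, n))
    for j in cols:
        mu = mu0.copy()
        mu[j] += h
        t.set_parameters(mu)
        up = t.map_point(point)
        mu[j] -= 2 * h
        t.set_parameters(mu)
        dn = t.map_point(point)
        out[:, j] = (up - dn) / (2 * h)
    t.set_parameters(mu0)
    return out
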