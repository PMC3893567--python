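"""Parametric coordinate transforms T_mu from the fixed to the moving domain.

Kinds: translation, rigid (Euler angles), similarity (rigid + isotropic
scale), affine, cubic B-spline free-form deformation, composition, and dense
displacement fields.  Each transform maps physical points (mm) to physical
points and exposes

* ``map_points`` — vectorized point mapping,
* ``parameter_jacobian`` — dT/dmu at a point, block-sparse for B-splines
  (only P = (O+1)^d basis products are computed instead of d*N entries),
* ``spatial_jacobian`` — dT/dx, whose determinant drives volume modulation,

plus module-level operations for transformation averaging (the unbiased
template-space construction), numerical inversion, and plain-text
serialization.

Parameter layouts
-----------------
translation : (t_1..t_d)
rigid       : d=2: (angle, t_1, t_2); d=3: (a_x, a_y, a_z, t_1..t_3) with
              R = R_z(a_z) @ R_y(a_y) @ R_x(a_x); rotation about ``center``
similarity  : rigid parameters followed by one isotropic scale s,
              T(x) = s R (x - c) + c + t
affine      : row-major A (d*d) followed by b, T(x) = A (x - c) + c + b
bspline     : d blocks of prod(grid_shape) control-point coefficients (mm),
              block k = displacement component k, C-order over the grid
composite   : concatenation of member parameter vectors; only the last
              (outermost) member is optimized during registration
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, NonConvergenceError
from .image import Geometry, voxel_to_world, world_to_voxel, write_vector_field, read_vector_field

__all__ = [
    "Transform",
    "TranslationTransform",
    "RigidTransform",
    "SimilarityTransform",
    "AffineTransform",
    "BSplineTransform",
    "CompositeTransform",
    "DisplacementFieldTransform",
    "SparseParameterJacobian",
    "SparseVector",
    "sparse_gradient_product",
    "average_transforms",
    "invert_transform",
    "bspline_grid_for",
    "write_transform",
    "read_transform",
    "displacement_field",
]


# ---------------------------------------------------------------------------
# cubic B-spline basis (uniform, order 3)
# ---------------------------------------------------------------------------

def _bspline3_weights(t):
    """Basis values for the 4 control points around a point; t = frac in [0,1)."""
    s = 1.0 - t
    return np.stack([
        s * s * s / 6.0,
        (3.0 * t**3 - 6.0 * t**2 + 4.0) / 6.0,
        (-3.0 * t**3 + 3.0 * t**2 + 3.0 * t + 1.0) / 6.0,
        t**3 / 6.0,
    ], axis=-1)


def _bspline3_dweights(t):
    s = 1.0 - t
    return np.stack([
        -0.5 * s * s,
        (3.0 * t**2 - 4.0 * t) / 2.0,
        (-3.0 * t**2 + 2.0 * t + 1.0) / 2.0,
        0.5 * t * t,
    ], axis=-1)


def _bspline3_ddweights(t):
    return np.stack([1.0 - t, 3.0 * t - 2.0, 1.0 - 3.0 * t, t], axis=-1)


# ---------------------------------------------------------------------------
# sparse containers
# ---------------------------------------------------------------------------

@dataclass
class SparseParameterJacobian:
    """The nonzero d x P block of dT/dmu plus its column index map.

    For a B-spline, ``values`` holds the P basis products j_1..j_P repeated on
    each of the d rows; row r of the dense d x N matrix has them in the
    disjoint column block ``nonzero_indices + r * block_size`` (the
    block-diagonal structure of the compact-support parameter Jacobian).  For
    the globally-supported kinds the container simply carries the dense
    Jacobian with ``nonzero_indices`` = all columns and ``block_size`` None.
    """

    values: np.ndarray          # (d, P)
    nonzero_indices: np.ndarray  # (P,)
    n_parameters: int
    block_size: int | None = None

    @property
    def P(self) -> int:
        return int(self.nonzero_indices.size)

    def to_dense(self) -> np.ndarray:
        d = self.values.shape[0]
        dense = np.zeros((d, self.n_parameters))
        if self.block_size is None:
            dense[:, self.nonzero_indices] = self.values
        else:
            for r in range(d):
                dense[r, self.nonzero_indices + r * self.block_size] = self.values[r]
        return dense


@dataclass
class SparseVector:
    """Sparse length-n vector as parallel (indices, values) arrays."""

    indices: np.ndarray
    values: np.ndarray
    n: int

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.n)
        np.add.at(out, self.indices, self.values)
        return out


def sparse_gradient_product(jac: SparseParameterJacobian, image_gradient) -> SparseVector:
    """J^T g restricted to the nonzero columns (d*P multiplications)."""
    g = np.asarray(image_gradient, dtype=float).reshape(-1)
    d = jac.values.shape[0]
    if g.size != d:
        raise ContractError(f"gradient length {g.size} != spatial dimension {d}")
    if jac.block_size is None:
        vals = g @ jac.values  # (P,)
        return SparseVector(jac.nonzero_indices.copy(), vals, jac.n_parameters)
    idx = np.concatenate([jac.nonzero_indices + r * jac.block_size for r in range(d)])
    vals = np.concatenate([g[r] * jac.values[r] for r in range(d)])
    return SparseVector(idx, vals, jac.n_parameters)


# ---------------------------------------------------------------------------
# base class
# ---------------------------------------------------------------------------

class Transform:
    kind = "base"

    def __init__(self, dimension: int):
        if dimension not in (2, 3):
            raise ContractError("dimension must be 2 or 3")
        self.dimension = int(dimension)

    # -- parameters ---------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return self.get_parameters().size

    def get_parameters(self) -> np.ndarray:
        raise NotImplementedError

    def set_parameters(self, mu) -> None:
        raise NotImplementedError

    # -- point mapping ------------------------------------------------------
    def map_points(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def map_point(self, point) -> np.ndarray:
        p = np.asarray(point, dtype=float).reshape(-1)
        if p.size != self.dimension:
            raise ContractError(
                f"point has length {p.size}, transform dimension is {self.dimension}")
        return self.map_points(p[None, :])[0]

    def _check_points(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != self.dimension:
            raise ContractError(
                f"points must be (n, {self.dimension}), got {pts.shape}")
        return pts

    # -- parameter Jacobian -------------------------------------------------
    def parameter_jacobian(self, point) -> SparseParameterJacobian:
        """dT/dmu at one physical point, in the sparse container."""
        raise NotImplementedError

    def jacobian_batch(self, points):
        """Vectorized parameter Jacobians for metric assembly.

        Returns ``("dense", J)`` with J of shape (n, d, N), or
        ``("sparse", weights, flat_indices, block_size)`` for the B-spline,
        where row r of sample i is nonzero at ``flat_indices[i] + r*block``.
        """
        pts = self._check_points(points)
        J = np.stack([self.parameter_jacobian(p).to_dense() for p in pts])
        return ("dense", J)

    # -- spatial Jacobian ---------------------------------------------------
    def spatial_jacobian_batch(self, points, h: float = 0.5) -> np.ndarray:
        """dT/dx at each point, shape (n, d, d); central differences by default."""
        pts = self._check_points(points)
        d = self.dimension
        J = np.empty((pts.shape[0], d, d))
        for a in range(d):
            e = np.zeros(d)
            e[a] = h
            J[:, :, a] = (self.map_points(pts + e) - self.map_points(pts - e)) / (2 * h)
        return J

    def spatial_jacobian(self, point) -> np.ndarray:
        p = np.asarray(point, dtype=float).reshape(1, -1)
        return self.spatial_jacobian_batch(p)[0]

    def spatial_jacobian_determinant(self, point) -> float:
        return float(np.linalg.det(self.spatial_jacobian(point)))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# globally supported kinds
# ---------------------------------------------------------------------------

class TranslationTransform(Transform):
    kind = "translation"

    def __init__(self, offset):
        offset = np.asarray(offset, dtype=float).reshape(-1)
        super().__init__(offset.size)
        self.offset = offset

    def get_parameters(self):
        return self.offset.copy()

    def set_parameters(self, mu):
        mu = np.asarray(mu, dtype=float).reshape(-1)
        if mu.size != self.dimension:
            raise ContractError("translation parameter length mismatch")
        self.offset = mu.copy()

    def map_points(self, points):
        return self._check_points(points) + self.offset

    def parameter_jacobian(self, point):
        d = self.dimension
        return SparseParameterJacobian(np.eye(d), np.arange(d), d)

    def jacobian_batch(self, points):
        pts = self._check_points(points)
        d = self.dimension
        return ("dense", np.broadcast_to(np.eye(d), (pts.shape[0], d, d)).copy())

    def spatial_jacobian_batch(self, points, h=0.5):
        pts = self._check_points(points)
        d = self.dimension
        return np.broadcast_to(np.eye(d), (pts.shape[0], d, d)).copy()

    def to_dict(self):
        return {"kind": self.kind, "dimension": self.dimension,
                "parameters": self.offset.tolist()}


def _rot2(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def _drot2(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[-s, -c], [c, -s]])


def _rot3_factors(ax, ay, az):
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    dRx = np.array([[0, 0, 0], [0, -sx, -cx], [0, cx, -sx]])
    dRy = np.array([[-sy, 0, cy], [0, 0, 0], [-cy, 0, -sy]])
    dRz = np.array([[-sz, -cz, 0], [cz, -sz, 0], [0, 0, 0]])
    return (Rx, Ry, Rz), (dRx, dRy, dRz)


class _LinearBase(Transform):
    """Common machinery for transforms of the form T(x) = M (x - c) + c + t."""

    def __init__(self, dimension, center=None):
        super().__init__(dimension)
        self.center = (np.zeros(dimension) if center is None
                       else np.asarray(center, dtype=float).reshape(dimension))

    def _matrix_offset(self):
        """Return (M, t) of T(x) = M (x - c) + c + t."""
        raise NotImplementedError

    def map_points(self, points):
        pts = self._check_points(points)
        M, t = self._matrix_offset()
        return (pts - self.center) @ M.T + self.center + t

    def spatial_jacobian_batch(self, points, h=0.5):
        pts = self._check_points(points)
        M, _ = self._matrix_offset()
        return np.broadcast_to(M, (pts.shape[0],) + M.shape).copy()

    def jacobian_batch(self, points):
        pts = self._check_points(points)
        return ("dense", np.stack([self.parameter_jacobian(p).to_dense() for p in pts]))


class RigidTransform(_LinearBase):
    kind = "rigid"

    def __init__(self, dimension, angles=0.0, translation=0.0, center=None):
        super().__init__(dimension, center)
        n_rot = 1 if dimension == 2 else 3
        self.angles = np.zeros(n_rot) + np.asarray(angles, dtype=float).reshape(-1)
        if self.angles.size != n_rot:
            raise ContractError(f"rigid d={dimension} needs {n_rot} angle(s)")
        self.translation = np.zeros(dimension) + np.asarray(translation, dtype=float).reshape(-1)
        if self.translation.size != dimension:
            raise ContractError("translation length mismatch")

    @property
    def _n_rot(self):
        return self.angles.size

    def _rotation(self):
        if self.dimension == 2:
            return _rot2(self.angles[0])
        (Rx, Ry, Rz), _ = _rot3_factors(*self.angles)
        return Rz @ Ry @ Rx

    def _rotation_derivatives(self):
        if self.dimension == 2:
            return [_drot2(self.angles[0])]
        (Rx, Ry, Rz), (dRx, dRy, dRz) = _rot3_factors(*self.angles)
        return [Rz @ Ry @ dRx, Rz @ dRy @ Rx, dRz @ Ry @ Rx]

    def _matrix_offset(self):
        return self._rotation(), self.translation

    def get_parameters(self):
        return np.concatenate([self.angles, self.translation])

    def set_parameters(self, mu):
        mu = np.asarray(mu, dtype=float).reshape(-1)
        if mu.size != self._n_rot + self.dimension:
            raise ContractError("rigid parameter length mismatch")
        self.angles = mu[: self._n_rot].copy()
        self.translation = mu[self._n_rot:].copy()

    def parameter_jacobian(self, point):
        p = np.asarray(point, dtype=float).reshape(self.dimension) - self.center
        d = self.dimension
        N = self._n_rot + d
        J = np.zeros((d, N))
        for a, dR in enumerate(self._rotation_derivatives()):
            J[:, a] = dR @ p
        J[:, self._n_rot:] = np.eye(d)
        return SparseParameterJacobian(J, np.arange(N), N)

    def to_dict(self):
        return {"kind": self.kind, "dimension": self.dimension,
                "parameters": self.get_parameters().tolist(),
                "center": self.center.tolist()}


class SimilarityTransform(RigidTransform):
    kind = "similarity"

    def __init__(self, dimension, angles=0.0, translation=0.0, scale=1.0, center=None):
        super().__init__(dimension, angles, translation, center)
        self.scale = float(scale)

    def _matrix_offset(self):
        return self.scale * self._rotation(), self.translation

    def get_parameters(self):
        return np.concatenate([self.angles, self.translation, [self.scale]])

    def set_parameters(self, mu):
        mu = np.asarray(mu, dtype=float).reshape(-1)
        if mu.size != self._n_rot + self.dimension + 1:
            raise ContractError("similarity parameter length mismatch")
        self.angles = mu[: self._n_rot].copy()
        self.translation = mu[self._n_rot: self._n_rot + self.dimension].copy()
        self.scale = float(mu[-1])

    def parameter_jacobian(self, point):
        p = np.asarray(point, dtype=float).reshape(self.dimension) - self.center
        d = self.dimension
        N = self._n_rot + d + 1
        J = np.zeros((d, N))
        for a, dR in enumerate(self._rotation_derivatives()):
            J[:, a] = self.scale * (dR @ p)
        J[:, self._n_rot: self._n_rot + d] = np.eye(d)
        J[:, -1] = self._rotation() @ p
        return SparseParameterJacobian(J, np.arange(N), N)

    def to_dict(self):
        return {"kind": self.kind, "dimension": self.dimension,
                "parameters": self.get_parameters().tolist(),
                "center": self.center.tolist()}


class AffineTransform(_LinearBase):
    kind = "affine"

    def __init__(self, dimension, matrix=None, offset=0.0, center=None):
        super().__init__(dimension, center)
        self.matrix = (np.eye(dimension) if matrix is None
                       else np.asarray(matrix, dtype=float).reshape(dimension, dimension))
        self.offset = np.zeros(dimension) + np.asarray(offset, dtype=float).reshape(-1)
        if self.offset.size != dimension:
            raise ContractError("offset length mismatch")

    def _matrix_offset(self):
        return self.matrix, self.offset

    def get_parameters(self):
        return np.concatenate([self.matrix.reshape(-1), self.offset])

    def set_parameters(self, mu):
        d = self.dimension
        mu = np.asarray(mu, dtype=float).reshape(-1)
        if mu.size != d * d + d:
            raise ContractError("affine parameter length mismatch")
        self.matrix = mu[: d * d].reshape(d, d).copy()
        self.offset = mu[d * d:].copy()

    def parameter_jacobian(self, point):
        p = np.asarray(point, dtype=float).reshape(self.dimension) - self.center
        d = self.dimension
        N = d * d + d
        J = np.zeros((d, N))
        for r in range(d):
            J[r, r * d: (r + 1) * d] = p
            J[r, d * d + r] = 1.0
        return SparseParameterJacobian(J, np.arange(N), N)

    def jacobian_batch(self, points):
        pts = self._check_points(points) - self.center
        n, d = pts.shape
        J = np.zeros((n, d, d * d + d))
        for r in range(d):
            J[:, r, r * d: (r + 1) * d] = pts
            J[:, r, d * d + r] = 1.0
        return ("dense", J)

    def inverse(self) -> "AffineTransform":
        """Closed-form inverse (same center)."""
        Minv = np.linalg.inv(self.matrix)
        # T(x) = M(x-c)+c+t  =>  T^-1(y) = Minv(y-c-t)+c = Minv(y-c)+c - Minv t
        return AffineTransform(self.dimension, Minv, -Minv @ self.offset, self.center)

    def to_dict(self):
        return {"kind": self.kind, "dimension": self.dimension,
                "parameters": self.get_parameters().tolist(),
                "center": self.center.tolist()}


# ---------------------------------------------------------------------------
# cubic B-spline free-form deformation
# ---------------------------------------------------------------------------

class BSplineTransform(Transform):
    """Displacement T(x) = x + sum_p c_p B3((x - grid)/spacing).

    ``grid_geometry`` describes the control-point lattice (identity
    direction); ``coefficients`` has shape (d, *grid_shape) in mm.  A point is
    *supported* when all (O+1)^d surrounding control points exist; outside the
    support the displacement is exactly zero.
    """

    kind = "bspline"
    order = 3

    def __init__(self, grid_geometry: Geometry, coefficients=None):
        super().__init__(grid_geometry.ndim)
        if not np.allclose(grid_geometry.direction, np.eye(grid_geometry.ndim)):
            raise ContractError("B-spline grids require identity direction")
        self.grid = grid_geometry
        d = self.dimension
        if coefficients is None:
            coefficients = np.zeros((d,) + tuple(grid_geometry.shape))
        self.coefficients = np.asarray(coefficients, dtype=float)
        if self.coefficients.shape != (d,) + tuple(grid_geometry.shape):
            raise ContractError(
                f"coefficients must have shape {(d,) + tuple(grid_geometry.shape)}")

    # -- parameters ---------------------------------------------------------
    @property
    def grid_size(self) -> int:
        return int(np.prod(self.grid.shape))

    @property
    def support_size(self) -> int:
        """P = (O+1)^d control points influence any supported point."""
        return (self.order + 1) ** self.dimension

    def get_parameters(self):
        return self.coefficients.reshape(-1).copy()

    def set_parameters(self, mu):
        mu = np.asarray(mu, dtype=float).reshape(-1)
        if mu.size != self.dimension * self.grid_size:
            raise ContractError("bspline parameter length mismatch")
        self.coefficients = mu.reshape(self.coefficients.shape).copy()

    # -- support bookkeeping -------------------------------------------------
    def _grid_coords(self, pts):
        return (pts - self.grid.origin) / self.grid.spacing

    def _support(self, pts):
        """Per-axis (base index, fractional part) and inside-support mask."""
        u = self._grid_coords(pts)
        fl = np.floor(u)
        base = fl.astype(np.int64) - 1
        frac = u - fl
        shape = np.asarray(self.grid.shape)
        inside = np.all((base >= 0) & (base + 3 <= shape - 1), axis=1)
        return base, frac, inside

    def _tensor_weights(self, base, frac, weight_fns):
        """Tensor-product weights (n, P) and flat control indices (n, P).

        ``weight_fns`` gives the per-axis 1-d weight function (value or
        derivative basis), enabling value / first / second derivative tensors.
        """
        n = base.shape[0]
        d = self.dimension
        per_axis_w = [weight_fns[a](frac[:, a]) for a in range(d)]   # (n,4)
        offs = np.arange(4)
        per_axis_i = [base[:, a, None] + offs for a in range(d)]      # (n,4)
        if d == 2:
            w = per_axis_w[0][:, :, None] * per_axis_w[1][:, None, :]
            idx = (per_axis_i[0][:, :, None] * self.grid.shape[1]
                   + per_axis_i[1][:, None, :])
        else:
            w = (per_axis_w[0][:, :, None, None]
                 * per_axis_w[1][:, None, :, None]
                 * per_axis_w[2][:, None, None, :])
            s1, s2 = self.grid.shape[1], self.grid.shape[2]
            idx = ((per_axis_i[0][:, :, None, None] * s1
                    + per_axis_i[1][:, None, :, None]) * s2
                   + per_axis_i[2][:, None, None, :])
        return w.reshape(n, -1), idx.reshape(n, -1)

    def parameter_weights(self, points):
        """(weights (n,P), flat indices (n,P), inside mask (n,)).

        Rows of unsupported points carry zero weights and index 0.
        """
        pts = self._check_points(points)
        base, frac, inside = self._support(pts)
        base = np.where(inside[:, None], base, 1)  # safe placeholder
        w, idx = self._tensor_weights(base, frac, [_bspline3_weights] * self.dimension)
        w = np.where(inside[:, None], w, 0.0)
        idx = np.where(inside[:, None], idx, 0)
        return w, idx, inside

    # -- mapping & Jacobians -------------------------------------------------
    def map_points(self, points):
        pts = self._check_points(points)
        w, idx, inside = self.parameter_weights(pts)
        out = pts.copy()
        flat = self.coefficients.reshape(self.dimension, -1)
        for r in range(self.dimension):
            out[:, r] += np.einsum("np,np->n", w, flat[r][idx])
        return out

    def parameter_jacobian(self, point):
        p = np.asarray(point, dtype=float).reshape(1, self.dimension)
        w, idx, inside = self.parameter_weights(p)
        N = self.dimension * self.grid_size
        if not inside[0]:
            empty = np.zeros((self.dimension, 0))
            return SparseParameterJacobian(empty, np.empty(0, dtype=np.int64), N,
                                           block_size=self.grid_size)
        vals = np.broadcast_to(w[0], (self.dimension, w.shape[1])).copy()
        return SparseParameterJacobian(vals, idx[0].copy(), N,
                                       block_size=self.grid_size)

    def jacobian_batch(self, points):
        w, idx, inside = self.parameter_weights(points)
        return ("sparse", w, idx, self.grid_size)

    def spatial_jacobian_batch(self, points, h=None):
        pts = self._check_points(points)
        base, frac, inside = self._support(pts)
        base = np.where(inside[:, None], base, 1)
        d = self.dimension
        flat = self.coefficients.reshape(d, -1)
        J = np.broadcast_to(np.eye(d), (pts.shape[0], d, d)).copy()
        for a in range(d):
            fns = [_bspline3_dweights if k == a else _bspline3_weights for k in range(d)]
            w, idx = self._tensor_weights(base, frac, fns)
            w = np.where(inside[:, None], w, 0.0) / self.grid.spacing[a]
            for r in range(d):
                J[:, r, a] += np.einsum("np,np->n", w, flat[r][idx])
        return J

    def second_derivative_weights(self, points):
        """Weights of d^2 u / dx_a dx_b for each axis pair, for bending energy.

        Returns (list over (a,b) with a<=b of (weights (n,P), multiplicity),
        flat indices (n,P), inside mask).  Weights are per physical mm^2.
        """
        pts = self._check_points(points)
        base, frac, inside = self._support(pts)
        base = np.where(inside[:, None], base, 1)
        d = self.dimension
        out = []
        idx_ref = None
        for a in range(d):
            for b in range(a, d):
                fns = []
                for k in range(d):
                    if k == a and k == b:
                        fns.append(_bspline3_ddweights)
                    elif k in (a, b):
                        fns.append(_bspline3_dweights)
                    else:
                        fns.append(_bspline3_weights)
                w, idx = self._tensor_weights(base, frac, fns)
                w = np.where(inside[:, None], w, 0.0)
                w = w / (self.grid.spacing[a] * self.grid.spacing[b])
                mult = 1.0 if a == b else 2.0  # symmetric off-diagonal pair
                out.append(((a, b), w, mult))
                idx_ref = idx
        idx_ref = np.where(inside[:, None], idx_ref, 0)
        return out, idx_ref, inside

    def to_dict(self):
        return {"kind": self.kind, "dimension": self.dimension,
                "grid": {"shape": list(self.grid.shape),
                         "spacing": self.grid.spacing.tolist(),
                         "origin": self.grid.origin.tolist()},
                "parameters": self.get_parameters().tolist()}


def bspline_grid_for(extent_low, extent_high, spacing) -> Geometry:
    """Control-point lattice whose cubic support covers [low, high] with margin.

    The grid origin sits two spacings below the low corner and the shape adds
    enough knots that every point of the box keeps its full (O+1)^d support.
    """
    low = np.asarray(extent_low, dtype=float).reshape(-1)
    high = np.asarray(extent_high, dtype=float).reshape(-1)
    d = low.size
    spacing = np.zeros(d) + np.asarray(spacing, dtype=float).reshape(-1)
    if np.any(spacing <= 0):
        raise ContractError("grid spacing must be positive")
    origin = low - 2.0 * spacing
    shape = np.ceil((high - origin) / spacing).astype(int) + 4
    return Geometry(tuple(shape), spacing, origin)


# ---------------------------------------------------------------------------
# composite and displacement field
# ---------------------------------------------------------------------------

class CompositeTransform(Transform):
    """Function composition T(x) = T_n(...T_2(T_1(x))); members[0] innermost.

    The parameter vector is the concatenation of member vectors, but the
    parameter Jacobian (and hence optimization) refers to the *last*, outermost
    member only, matching staged registration where earlier stages are frozen.
    """

    kind = "composite"

    def __init__(self, members):
        members = list(members)
        if not members:
            raise ContractError("composite member list must be non-empty")
        dims = {m.dimension for m in members}
        if len(dims) != 1:
            raise ContractError("composite members must share a dimension")
        super().__init__(members[0].dimension)
        self.members = members

    @property
    def optimized(self) -> Transform:
        return self.members[-1]

    def get_parameters(self):
        return np.concatenate([m.get_parameters() for m in self.members])

    def set_parameters(self, mu):
        mu = np.asarray(mu, dtype=float).reshape(-1)
        sizes = [m.n_parameters for m in self.members]
        if mu.size != sum(sizes):
            raise ContractError("composite parameter length mismatch")
        pos = 0
        for m, s in zip(self.members, sizes):
            m.set_parameters(mu[pos: pos + s])
            pos += s

    def map_points(self, points):
        pts = self._check_points(points)
        for m in self.members:
            pts = m.map_points(pts)
        return pts

    def _inner_points(self, points):
        pts = self._check_points(points)
        for m in self.members[:-1]:
            pts = m.map_points(pts)
        return pts

    def parameter_jacobian(self, point):
        p = np.asarray(point, dtype=float).reshape(1, -1)
        return self.optimized.parameter_jacobian(self._inner_points(p)[0])

    def jacobian_batch(self, points):
        return self.optimized.jacobian_batch(self._inner_points(points))

    def spatial_jacobian_batch(self, points, h=0.5):
        pts = self._check_points(points)
        J = self.members[0].spatial_jacobian_batch(pts, h)
        chained = self.members[0].map_points(pts)
        for m in self.members[1:]:
            J = np.einsum("nij,njk->nik", m.spatial_jacobian_batch(chained, h), J)
            chained = m.map_points(chained)
        return J

    def to_dict(self):
        return {"kind": self.kind, "dimension": self.dimension,
                "members": [m.to_dict() for m in self.members]}


class DisplacementFieldTransform(Transform):
    """Dense displacement field on a voxel lattice, linearly interpolated.

    ``field`` has shape ``geometry.shape + (d,)`` (mm).  Outside the lattice
    the displacement is zero (identity).  Produced by transformation averaging
    and inversion, which are closed over this representation.
    """

    kind = "displacement_field"

    def __init__(self, geometry: Geometry, field: np.ndarray):
        super().__init__(geometry.ndim)
        field = np.asarray(field, dtype=float)
        if field.shape != tuple(geometry.shape) + (geometry.ndim,):
            raise ContractError("field shape must be geometry.shape + (d,)")
        self.geometry = geometry
        self.field = field
        self.max_residual: float | None = None  # set by invert_transform

    def get_parameters(self):
        return self.field.reshape(-1).copy()

    def set_parameters(self, mu):
        mu = np.asarray(mu, dtype=float).reshape(-1)
        if mu.size != self.field.size:
            raise ContractError("field parameter length mismatch")
        self.field = mu.reshape(self.field.shape).copy()

    def displacements(self, points):
        pts = self._check_points(points)
        idx = world_to_voxel(self.geometry, pts)
        shape = np.asarray(self.geometry.shape)
        inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
        base = np.clip(np.floor(idx).astype(np.int64), 0, np.maximum(shape - 2, 0))
        frac = idx - base
        d = self.dimension
        out = np.zeros((pts.shape[0], d))
        for corner in np.ndindex(*([2] * d)):
            w = np.ones(pts.shape[0])
            gather = []
            for a in range(d):
                w = w * (frac[:, a] if corner[a] else (1.0 - frac[:, a]))
                gather.append(np.minimum(base[:, a] + corner[a], shape[a] - 1))
            out += w[:, None] * self.field[tuple(gather)]
        out[~inside] = 0.0
        return out

    def map_points(self, points):
        pts = self._check_points(points)
        return pts + self.displacements(pts)

    def parameter_jacobian(self, point):
        raise NotImplementedError(
            "displacement-field transforms are not optimized parametrically")

    def spatial_jacobian_batch(self, points, h=None):
        if h is None:
            h = 0.5 * float(np.min(self.geometry.spacing))
        return super().spatial_jacobian_batch(points, h)

    def to_dict(self):
        return {"kind": self.kind, "dimension": self.dimension,
                "geometry": {"shape": list(self.geometry.shape),
                             "spacing": self.geometry.spacing.tolist(),
                             "origin": self.geometry.origin.tolist()}}


# ---------------------------------------------------------------------------
# averaging, inversion, dense fields
# ---------------------------------------------------------------------------

def displacement_field(transform: Transform, geometry: Geometry) -> np.ndarray:
    """Materialize T(x) - x on the voxel grid, shape ``geometry.shape + (d,)``."""
    pts = geometry.grid_points()
    disp = transform.map_points(pts) - pts
    return disp.reshape(tuple(geometry.shape) + (geometry.ndim,))


def average_transforms(transforms, geometry: Geometry,
                       include_identity: bool = False) -> DisplacementFieldTransform:
    """Pointwise average U(x) = (1/N) sum_j W_j(x) sampled on a voxel grid.

    When ``include_identity`` the identity map counts as one extra member,
    mirroring the unbiased template construction where a subject's own
    (identity) transformation participates in the average.
    """
    transforms = list(transforms)
    if not transforms:
        raise ContractError("average_transforms requires a non-empty list")
    pts = geometry.grid_points()
    acc = np.zeros_like(pts)
    for t in transforms:
        acc += t.map_points(pts)
    n = len(transforms)
    if include_identity:
        acc += pts
        n += 1
    mean = acc / n
    field = (mean - pts).reshape(tuple(geometry.shape) + (geometry.ndim,))
    return DisplacementFieldTransform(geometry, field)


def invert_transform(transform: Transform, geometry: Geometry,
                     tolerance: float = 0.01, max_iter: int = 50
                     ) -> DisplacementFieldTransform:
    """Numerical inverse V of U on a voxel grid by damped fixed-point iteration.

    Iterates v <- v - damp * (U(x + v) - x) (damping 1.0, halving to 0.5 when
    the worst residual increases) until max_x ||U(V(x)) - x|| <= tolerance mm.
    The achieved maximum residual is stored on the result as ``max_residual``.
    Raises :class:`NonConvergenceError` carrying the worst residual and its
    location if the tolerance is not met within ``max_iter`` iterations.
    """
    pts = geometry.grid_points()
    v = np.zeros_like(pts)
    damp = 1.0
    res = transform.map_points(pts + v) - pts
    worst = float(np.max(np.linalg.norm(res, axis=1))) if pts.size else 0.0
    for _ in range(max_iter):
        if worst <= tolerance:
            break
        v_new = v - damp * res
        res_new = transform.map_points(pts + v_new) - pts
        worst_new = float(np.max(np.linalg.norm(res_new, axis=1)))
        if worst_new > worst and damp > 0.5:
            damp = 0.5
            continue
        v, res, worst = v_new, res_new, worst_new
    if worst > tolerance:
        norms = np.linalg.norm(res, axis=1)
        i = int(np.argmax(norms))
        raise NonConvergenceError(
            f"inversion residual {worst:.4g} mm > tolerance {tolerance} mm",
            residual=worst, location=pts[i])
    out = DisplacementFieldTransform(
        geometry, v.reshape(tuple(geometry.shape) + (geometry.ndim,)))
    out.max_residual = worst
    return out


# ---------------------------------------------------------------------------
# serialization (plain text)
# ---------------------------------------------------------------------------

def _from_dict(obj: dict, base_path: str | None = None) -> Transform:
    kind = obj["kind"]
    d = int(obj.get("dimension", 3))
    if kind == "translation":
        return TranslationTransform(obj["parameters"])
    if kind == "rigid":
        t = RigidTransform(d, center=obj.get("center", None))
        t.set_parameters(obj["parameters"])
        return t
    if kind == "similarity":
        t = SimilarityTransform(d, center=obj.get("center", None))
        t.set_parameters(obj["parameters"])
        return t
    if kind == "affine":
        t = AffineTransform(d, center=obj.get("center", None))
        t.set_parameters(obj["parameters"])
        return t
    if kind == "bspline":
        g = obj["grid"]
        grid = Geometry(tuple(g["shape"]), g["spacing"], g["origin"])
        t = BSplineTransform(grid)
        t.set_parameters(obj["parameters"])
        return t
    if kind == "composite":
        return CompositeTransform([_from_dict(m, base_path) for m in obj["members"]])
    if kind == "displacement_field":
        field_path = obj["field_file"]
        if base_path is not None and not os.path.isabs(field_path):
            field_path = os.path.join(base_path, field_path)
        field, geom = read_vector_field(field_path)
        return DisplacementFieldTransform(geom, field)
    raise ContractError(f"unknown transform kind {kind!r}")


def write_transform(transform: Transform, path) -> None:
    """Serialize to a plain-text (JSON) parameter file.

    Displacement fields are written as a vector MetaImage next to the
    parameter file; the parameter file references it by name.
    """
    path = str(path)
    obj = transform.to_dict()

    def attach_fields(o, t, stem):
        if t.kind == "displacement_field":
            field_file = stem + ".field.mha"
            write_vector_field(t.field, t.geometry, field_file)
            o["field_file"] = os.path.basename(field_file)
        elif t.kind == "composite":
            for i, (mo, mt) in enumerate(zip(o["members"], t.members)):
                attach_fields(mo, mt, f"{stem}.m{i}")

    attach_fields(obj, transform, os.path.splitext(path)[0])
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def read_transform(path) -> Transform:
    with open(path) as fh:
        obj = json.load(fh)
    return _from_dict(obj, base_path=os.path.dirname(str(path)))
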