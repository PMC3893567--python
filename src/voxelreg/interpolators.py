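"""Image value and gradient evaluation at non-voxel physical positions.

Kinds: nearest-neighbor, linear, and B-spline of order 1 and 3.  Linear and
first-order B-spline produce identical values; the linear kind additionally
carries the fast analytic gradient path used when assembling metric
derivatives.  The cubic kind prefilters the image into B-spline coefficients
(recursive filter, mirror boundary) so that interpolation reproduces voxel
values at voxel centers.

Evaluation outside the image domain (the closed box of voxel centers) returns
``outside_value``; an inside-domain predicate is exposed alongside so callers
such as the metric sampler can instead drop those points.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ContractError, UnsupportedOperationError
from .image import Image, world_to_voxel
from .transforms import _bspline3_weights, _bspline3_dweights

__all__ = ["Interpolator", "make_interpolator", "INTERPOLATOR_KINDS"]

INTERPOLATOR_KINDS = ("nearest", "linear", "bspline1", "bspline3")


def _mirror_indices(idx, n):
    """Reflect integer indices into [0, n-1] about the edge voxel centers."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * (n - 1)
    m = np.mod(idx, period)
    return np.where(m >= n, period - m, m)


class Interpolator:
    """Continuous image model over a scalar :class:`Image`."""

    def __init__(self, kind: str, image: Image, outside_value: float = 0.0):
        if kind not in INTERPOLATOR_KINDS:
            raise ContractError(f"unknown interpolator kind {kind!r}")
        self.kind = kind
        self.image = image
        self.outside_value = float(outside_value)
        self._shape = np.asarray(image.shape)
        # physical gradient conversion: index = diag(1/spacing) D^T (x - origin)
        # so dI/dx = D diag(1/spacing) dI/didx
        self._grad_matrix = image.direction * (1.0 / image.spacing)[None, :]
        if kind == "bspline3":
            self.coefficient_cache = ndimage.spline_filter(
                np.asarray(image.data, dtype=np.float64), order=3, mode="mirror")
        else:
            self.coefficient_cache = None

    # -- geometry helpers ---------------------------------------------------
    def _indices(self, points):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != self.image.ndim:
            raise ContractError(f"points must be (n, {self.image.ndim})")
        return world_to_voxel(self.image.geometry, pts)

    def is_inside(self, points) -> np.ndarray:
        """Boolean mask: does each point lie in the closed voxel-center box?"""
        idx = self._indices(points)
        return np.all((idx >= 0) & (idx <= self._shape - 1), axis=1)

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, points) -> np.ndarray:
        """Interpolated intensities at (n, d) physical points."""
        idx = self._indices(points)
        inside = np.all((idx >= 0) & (idx <= self._shape - 1), axis=1)
        out = np.full(idx.shape[0], self.outside_value, dtype=float)
        if not inside.any():
            return out
        out[inside] = self._evaluate_inside(idx[inside])
        return out

    def evaluate_point(self, point) -> float:
        return float(self.evaluate(np.asarray(point, dtype=float)[None, :])[0])

    def _evaluate_inside(self, idx):
        if self.kind == "nearest":
            # round half away from zero, componentwise (indices are >= 0 here)
            nn = np.floor(idx + 0.5).astype(np.int64)
            nn = np.minimum(nn, self._shape - 1)
            return self.image.data[tuple(nn.T)].astype(float)
        if self.kind in ("linear", "bspline1"):
            val, _ = self._linear(idx, want_gradient=False)
            return val
        val, _ = self._cubic(idx, want_gradient=False)
        return val

    # -- gradients ----------------------------------------------------------
    def evaluate_gradient(self, points) -> np.ndarray:
        """Analytic spatial gradient (intensity per mm), (n, d).

        Outside the domain the gradient is zero.  Nearest-neighbor has no
        gradient and raises :class:`UnsupportedOperationError`.
        """
        if self.kind == "nearest":
            raise UnsupportedOperationError(
                "nearest-neighbor interpolation has no gradient")
        idx = self._indices(points)
        inside = np.all((idx >= 0) & (idx <= self._shape - 1), axis=1)
        grad = np.zeros((idx.shape[0], self.image.ndim))
        if inside.any():
            if self.kind in ("linear", "bspline1"):
                _, g = self._linear(idx[inside], want_gradient=True)
            else:
                _, g = self._cubic(idx[inside], want_gradient=True)
            grad[inside] = g @ self._grad_matrix.T
        return grad

    def evaluate_with_gradient(self, points):
        """(values, physical gradients) in one pass, for metric assembly."""
        if self.kind == "nearest":
            raise UnsupportedOperationError(
                "nearest-neighbor interpolation has no gradient")
        idx = self._indices(points)
        inside = np.all((idx >= 0) & (idx <= self._shape - 1), axis=1)
        vals = np.full(idx.shape[0], self.outside_value, dtype=float)
        grad = np.zeros((idx.shape[0], self.image.ndim))
        if inside.any():
            if self.kind in ("linear", "bspline1"):
                v, g = self._linear(idx[inside], want_gradient=True)
            else:
                v, g = self._cubic(idx[inside], want_gradient=True)
            vals[inside] = v
            grad[inside] = g @ self._grad_matrix.T
        return vals, grad, inside

    # -- kernels ------------------------------------------------------------
    def _linear(self, idx, want_gradient):
        d = self.image.ndim
        data = self.image.data
        base = np.floor(idx).astype(np.int64)
        base = np.clip(base, 0, np.maximum(self._shape - 2, 0))
        frac = idx - base
        val = np.zeros(idx.shape[0])
        grad = np.zeros((idx.shape[0], d)) if want_gradient else None
        for corner in np.ndindex(*([2] * d)):
            w = np.ones(idx.shape[0])
            gather = []
            for a in range(d):
                w = w * (frac[:, a] if corner[a] else (1.0 - frac[:, a]))
                gather.append(np.minimum(base[:, a] + corner[a], self._shape[a] - 1))
            v = data[tuple(gather)].astype(float)
            val += w * v
            if want_gradient:
                for a in range(d):
                    wg = np.ones(idx.shape[0])
                    for b in range(d):
                        if b == a:
                            wg = wg * (1.0 if corner[b] else -1.0)
                        else:
                            wg = wg * (frac[:, b] if corner[b] else (1.0 - frac[:, b]))
                    grad[:, a] += wg * v
        return val, grad

    def _cubic(self, idx, want_gradient):
        d = self.image.ndim
        coeff = self.coefficient_cache
        fl = np.floor(idx)
        base = fl.astype(np.int64) - 1
        frac = idx - fl
        w_ax = [_bspline3_weights(frac[:, a]) for a in range(d)]
        dw_ax = [_bspline3_dweights(frac[:, a]) for a in range(d)] if want_gradient else None
        i_ax = [
            _mirror_indices(base[:, a, None] + np.arange(4), int(self._shape[a]))
            for a in range(d)
        ]
        val = np.zeros(idx.shape[0])
        grad = np.zeros((idx.shape[0], d)) if want_gradient else None
        for taps in np.ndindex(*([4] * d)):
            w = np.ones(idx.shape[0])
            gather = []
            for a in range(d):
                w = w * w_ax[a][:, taps[a]]
                gather.append(i_ax[a][:, taps[a]])
            c = coeff[tuple(gather)]
            val += w * c
            if want_gradient:
                for a in range(d):
                    wg = dw_ax[a][:, taps[a]].copy()
                    for b in range(d):
                        if b != a:
                            wg = wg * w_ax[b][:, taps[b]]
                    grad[:, a] += wg * c
        return val, grad


def make_interpolator(kind: str, image: Image, outside_value: float = 0.0) -> Interpolator:
    return Interpolator(kind, image, outside_value)
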