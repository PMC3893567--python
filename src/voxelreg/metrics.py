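"""Similarity metrics and their analytic derivatives over a stochastic sample set.

The cost derivative is assembled as the normalized sample sum

    g = eta * sum_{x in sample set} xi(x) . J(x)^T dI_M/dx,

with J = dT/dmu the (block-sparse for B-splines) parameter Jacobian, eta the
reciprocal of the number of samples that mapped inside the moving domain, and
xi the metric-specific per-sample factor.  Samples whose mapped point falls
outside the moving image are dropped and eta recomputed over the remainder.

All metrics are costs to *minimize*:

* ``msd``  mean squared intensity difference, eta sum (I_F - I_M(T(x)))^2
* ``nc``   1 - NC^2, with NC the normalized (Pearson) correlation of the
  sampled fixed and transformed-moving intensities
* ``mi``   negated mutual information, Mattes-style Parzen estimate with a
  fixed number of histogram bins, zero-order window on the fixed intensity
  and cubic window on the moving intensity

plus the bending-energy penalty (squared Frobenius norm of the second spatial
derivative of the transform), which vanishes identically for affine motion.

``evaluate_partitioned`` realizes the fork-join contract: the per-sample
accumulation is split over T disjoint contiguous partitions whose partial
derivatives are then joined; for any T the result matches the single-
partition sum up to floating-point reassociation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (ContractError, DegenerateInputError,
                     DegenerateOverlapError, UnsupportedOperationError)
from .image import Image, LabelImage, voxel_to_world
from .interpolators import Interpolator, make_interpolator
from .transforms import BSplineTransform, CompositeTransform, Transform

__all__ = [
    "SampleSet",
    "MetricReport",
    "PartialDerivative",
    "draw_samples",
    "metric_value_and_derivative",
    "bending_energy_value_and_derivative",
    "evaluate_partitioned",
    "join_partials",
    "METRIC_KINDS",
]

METRIC_KINDS = ("msd", "nc", "mi")

_DEFAULT_BINS = 32


@dataclass
class SampleSet:
    """The stochastic subset of fixed-domain points used in one iteration."""

    points: np.ndarray          # (n, d) physical points
    seed: int
    iteration: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def count(self) -> int:
        return self.points.shape[0]

    @property
    def eta(self) -> float:
        """Normalizer 1 / |sample set| (before overlap exclusion)."""
        return 1.0 / self.count


@dataclass
class MetricReport:
    value: float
    derivative: np.ndarray
    samples_used: int


@dataclass
class PartialDerivative:
    """Partition-mean derivative contribution of one fork-join worker."""

    values: np.ndarray
    thread_id: int
    samples_in_partition: int


def draw_samples(fixed: Image, mask: LabelImage | None, count: int,
                 seed: int, iteration: int = 0) -> SampleSet:
    """Uniform random physical points over the fixed domain.

    Deterministic given (seed, iteration) via a counter-keyed generator, so
    iteration-k sample sets are reproducible without sequential RNG state.
    With a mask, points are rejection-sampled until ``count`` fall on nonzero
    mask voxels (nearest-voxel lookup).
    """
    if count < 1:
        raise ContractError("sample count must be >= 1")
    if mask is not None and not np.any(mask.data):
        raise DegenerateInputError("mask has no nonzero voxels")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(iteration)])
    shape = np.asarray(fixed.shape, dtype=float)
    collected = []
    n_have = 0
    attempts = 0
    while n_have < count:
        n_draw = count - n_have if mask is None else max(2 * (count - n_have), 64)
        idx = rng.uniform(0.0, shape - 1.0, size=(n_draw, fixed.ndim))
        if mask is not None:
            vox = np.clip(np.rint(idx).astype(np.int64), 0,
                          (shape - 1).astype(np.int64))
            keep = mask.data[tuple(vox.T)] > 0
            idx = idx[keep]
        collected.append(idx)
        n_have += idx.shape[0]
        attempts += 1
        if attempts > 10000:  # pragma: no cover - defensive
            raise DegenerateInputError("mask rejection sampling failed to converge")
    pts_idx = np.concatenate(collected)[:count]
    return SampleSet(voxel_to_world(fixed.geometry, pts_idx),
                     seed=int(seed), iteration=int(iteration))


# ---------------------------------------------------------------------------
# per-sample xi factors
# ---------------------------------------------------------------------------

def _msd(fixed_vals, moving_vals):
    resid = moving_vals - fixed_vals
    n = fixed_vals.size
    value = float(np.sum(resid * resid) / n)
    # d/dm_i of (1/n) sum (m - f)^2
    xi = 2.0 * resid / n
    return value, xi


def _nc(fixed_vals, moving_vals):
    n = fixed_vals.size
    f = fixed_vals - fixed_vals.mean()
    m = moving_vals - moving_vals.mean()
    sff = float(f @ f)
    smm = float(m @ m)
    sfm = float(f @ m)
    if sff <= 0 or smm <= 0:
        # constant image(s): correlation undefined; flat cost, zero derivative
        return 1.0, np.zeros(n)
    nc = sfm / np.sqrt(sff * smm)
    value = 1.0 - nc * nc
    dnc_dm = (f - (sfm / smm) * m) / np.sqrt(sff * smm)
    xi = -2.0 * nc * dnc_dm
    return float(value), xi


def _parzen_cubic(t):
    """Cubic B-spline Parzen window on [-2, 2] and its derivative."""
    at = np.abs(t)
    w = np.where(at < 1.0,
                 (4.0 - 6.0 * at**2 + 3.0 * at**3) / 6.0,
                 np.where(at < 2.0, (2.0 - at) ** 3 / 6.0, 0.0))
    dw = np.where(at < 1.0,
                  (-12.0 * at + 9.0 * at**2) / 6.0,
                  np.where(at < 2.0, -0.5 * (2.0 - at) ** 2, 0.0))
    return w, dw * np.sign(t)


def _mi(fixed_vals, moving_vals, fixed_range, moving_range, bins):
    """Negated Mattes mutual information and d(-MI)/dm_i.

    Bin edges derive from the *global* image intensity ranges (not the sample
    batch), so the estimate is a smooth function of the moving samples.
    Fixed intensities use a zero-order (nearest-bin) window; moving
    intensities a cubic Parzen window spread over four bins.
    """
    n = fixed_vals.size
    f_lo, f_hi = fixed_range
    m_lo, m_hi = moving_range
    f_w = max(f_hi - f_lo, 1e-12) / bins
    kf = np.clip(((fixed_vals - f_lo) / f_w).astype(np.int64), 0, bins - 1)
    m_w = max(m_hi - m_lo, 1e-12) / (bins - 5)
    cm = (moving_vals - m_lo) / m_w + 2.0
    cm = np.clip(cm, 2.0, bins - 3.0)

    base = np.floor(cm).astype(np.int64)
    taps = base[:, None] + np.arange(-1, 3)
    w, dw = _parzen_cubic(taps - cm[:, None])

    joint = np.zeros((bins, bins))
    np.add.at(joint, (kf[:, None].repeat(4, axis=1), taps), w)
    joint /= n
    p_m = joint.sum(axis=0)
    p_f = joint.sum(axis=1)

    nz = joint > 0
    log_term = np.zeros_like(joint)
    log_term[nz] = np.log(joint[nz] / (p_f[:, None] * p_m[None, :])[nz])
    mi = float(np.sum(joint[nz] * log_term[nz]))

    # d(-MI)/dcm_i = (1/n) sum_taps dW(tap - cm) * log(joint/p_m) at (kf_i, tap)
    log_jm = np.zeros_like(joint)
    log_jm[nz] = np.log(joint[nz] / p_m[None, :].repeat(bins, axis=0)[nz])
    per_tap = log_jm[kf[:, None].repeat(4, axis=1), taps]
    xi = np.sum(dw * per_tap, axis=1) / (n * m_w)
    clipped = (cm <= 2.0) | (cm >= bins - 3.0)
    xi[clipped] = 0.0
    return -mi, xi


# ---------------------------------------------------------------------------
# derivative assembly
# ---------------------------------------------------------------------------

def _accumulate(transform: Transform, points, grads, xi, partition_bounds):
    """Per-partition mean of xi_i * J_i^T grad_i; returns list of partial sums.

    ``partition_bounds`` is a list of (start, stop) into the included-sample
    arrays.  Uses the sparse block path when the (possibly composite)
    transform ends in a B-spline, costing O(d P) per sample instead of O(d N).
    """
    kind, *payload = transform.jacobian_batch(points)
    partials = []
    if kind == "sparse":
        w, idx, block = payload
        d = points.shape[1]
        n_par = transform.optimized.n_parameters if isinstance(
            transform, CompositeTransform) else transform.n_parameters
        for start, stop in partition_bounds:
            g = np.zeros(n_par)
            sl = slice(start, stop)
            contrib = xi[sl, None] * w[sl]
            for r in range(d):
                np.add.at(g, idx[sl] + r * block, contrib * grads[sl, r:r + 1])
            partials.append(g / max(stop - start, 1))
    else:
        J = payload[0]  # (n, d, N)
        for start, stop in partition_bounds:
            sl = slice(start, stop)
            g = np.einsum("n,nd,ndp->p", xi[sl], grads[sl], J[sl])
            partials.append(g / max(stop - start, 1))
    return partials


def join_partials(partials, eta: float) -> np.ndarray:
    """Aggregate fork-join partial derivatives into the single derivative.

    Weighted sum of the partition-mean vectors (weights = partition sample
    counts) times eta; over disjoint index ranges the join is itself
    parallelizable with bit-identical results, being pure elementwise sums.
    """
    if not partials:
        raise ContractError("no partials to join")
    n = partials[0].values.size
    out = np.zeros(n)
    for p in partials:
        if p.values.size != n:
            raise ContractError("partial derivative length mismatch")
        out += p.samples_in_partition * p.values
    return eta * out


def _metric_core(metric: str, fixed: Image, moving_interp: Interpolator,
                 transform: Transform, samples: SampleSet,
                 partitions: int, histogram_bins: int,
                 fixed_interp: Interpolator | None):
    if metric not in METRIC_KINDS:
        raise ContractError(f"metric must be one of {METRIC_KINDS}")
    if partitions < 1:
        raise ContractError("partition count must be >= 1")
    if partitions > samples.count:
        raise ContractError(
            f"partition count {partitions} exceeds sample count {samples.count}")

    pts = samples.points
    if fixed_interp is None:
        fixed_interp = make_interpolator("linear", fixed)
    fixed_vals_all = fixed_interp.evaluate(pts)
    mapped = transform.map_points(pts)
    m_vals_all, m_grads_all, inside = moving_interp.evaluate_with_gradient(mapped)

    included = np.flatnonzero(inside)
    n_inc = included.size
    if n_inc < 2:
        raise DegenerateOverlapError(
            f"only {n_inc} of {samples.count} samples mapped inside the moving domain")
    eta = 1.0 / n_inc

    f = fixed_vals_all[included]
    m = m_vals_all[included]
    grads = m_grads_all[included]
    pts_inc = pts[included]

    if metric == "msd":
        value, xi = _msd(f, m)
    elif metric == "nc":
        value, xi = _nc(f, m)
    else:
        fr = (float(fixed.data.min()), float(fixed.data.max()))
        mr = (float(moving_interp.image.data.min()),
              float(moving_interp.image.data.max()))
        value, xi = _mi(f, m, fr, mr, histogram_bins)

    # xi already carries the 1/n normalization of the value expressions above;
    # rescale to per-sample so the eta-weighted join reproduces it
    xi_per_sample = xi * n_inc

    bounds_idx = np.array_split(np.arange(n_inc), partitions)
    bounds = [(b[0], b[-1] + 1) if b.size else (0, 0) for b in bounds_idx]
    partial_vecs = _accumulate(transform, pts_inc, grads, xi_per_sample, bounds)
    partials = [PartialDerivative(v, t, b[1] - b[0])
                for t, (v, b) in enumerate(zip(partial_vecs, bounds))]
    derivative = join_partials(partials, eta)
    return MetricReport(value, derivative, n_inc), partials


def metric_value_and_derivative(metric: str, fixed: Image,
                                moving_interp: Interpolator,
                                transform: Transform, samples: SampleSet,
                                histogram_bins: int = _DEFAULT_BINS,
                                fixed_interp: Interpolator | None = None
                                ) -> MetricReport:
    """Metric value and analytic derivative over the sample set (T = 1)."""
    report, _ = _metric_core(metric, fixed, moving_interp, transform, samples,
                             1, histogram_bins, fixed_interp)
    return report


def evaluate_partitioned(metric: str, fixed: Image, moving_interp: Interpolator,
                         transform: Transform, samples: SampleSet,
                         partitions: int, histogram_bins: int = _DEFAULT_BINS,
                         fixed_interp: Interpolator | None = None
                         ) -> MetricReport:
    """Fork-join evaluation over T disjoint contiguous sample partitions."""
    report, _ = _metric_core(metric, fixed, moving_interp, transform, samples,
                             partitions, histogram_bins, fixed_interp)
    return report


# ---------------------------------------------------------------------------
# bending energy
# ---------------------------------------------------------------------------

def _bspline_member(transform: Transform):
    if isinstance(transform, BSplineTransform):
        return transform, None
    if isinstance(transform, CompositeTransform) and isinstance(
            transform.optimized, BSplineTransform):
        return transform.optimized, transform
    raise UnsupportedOperationError(
        "bending energy is defined for B-spline transforms only")


def bending_energy_value_and_derivative(transform: Transform,
                                        samples: SampleSet) -> MetricReport:
    """eta-weighted sample sum of ||d^2 T / dx^2||_F^2 with analytic derivative.

    Exactly zero (value and derivative) whenever the displacement is globally
    affine in x, since the cubic B-spline second derivative annihilates
    affine functions.  For a composite the penalty applies to the optimized
    (outermost) B-spline member, evaluated at the chained points.
    """
    bspline, composite = _bspline_member(transform)
    pts = samples.points
    if composite is not None:
        pts = composite._inner_points(pts)
    n = pts.shape[0]
    d = bspline.dimension
    flat = bspline.coefficients.reshape(d, -1)

    pairs, idx, inside = bspline.second_derivative_weights(pts)
    value = 0.0
    deriv = np.zeros(bspline.n_parameters)
    G = bspline.grid_size
    for (a, b), w, mult in pairs:
        for r in range(d):
            h = np.einsum("np,np->n", w, flat[r][idx])  # (n,)
            value += mult * float(h @ h)
            np.add.at(deriv, idx + r * G,
                      (2.0 * mult / n) * h[:, None] * w)
    value /= n
    return MetricReport(value, deriv, int(inside.sum()))
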