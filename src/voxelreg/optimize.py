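"""Iterative stochastic gradient-descent registration in a multi-resolution loop.

Each iteration draws a fresh random sample set, evaluates the metric value
and analytic derivative over it (optionally fork-joined over T partitions),
and updates the parameters with the decaying gain

    mu_{k+1} = mu_k - a_k g_k,        a_k = a / (A + k)^alpha.

The registration driver stages transform models of increasing flexibility
(e.g. similarity -> affine -> B-spline), composing each new stage with the
frozen previous ones, and runs every stage coarse-to-fine over the Gaussian
pyramid levels.  The B-spline control grid is refined (spacing halved) from
one resolution to the next so that progressively more parameters are used.

The automatic (adaptive) step-size estimation of ASGD-style optimizers is
deliberately out of scope; the classical decaying gain above is exposed in
the configuration instead.  Because a raw gradient step is badly
scale-dependent across transform kinds and intensity ranges, the driver by
default normalizes the derivative by its max-norm before applying the gain,
so ``a`` reads as an initial parameter step in physical units (mm).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateOverlapError, NumericalError
from .image import Geometry, Image, LabelImage
from .interpolators import make_interpolator
from .metrics import (SampleSet, bending_energy_value_and_derivative,
                      draw_samples, evaluate_partitioned)
from .pyramid import PyramidSchedule, build_pyramid
from .resample import resample
from .transforms import (AffineTransform, BSplineTransform, CompositeTransform,
                         RigidTransform, SimilarityTransform, Transform,
                         TranslationTransform, bspline_grid_for)

__all__ = [
    "GainSchedule",
    "RegistrationConfig",
    "IterationLog",
    "IterationRecord",
    "gradient_descent_step",
    "run_resolution",
    "refine_bspline_grid",
    "register",
]

STAGE_KINDS = ("translation", "rigid", "similarity", "affine", "bspline")


@dataclass
class GainSchedule:
    """Decaying step size a_k = a / (A + k)^alpha."""

    a: float = 1.0
    A: float = 20.0
    alpha: float = 0.602

    def __post_init__(self):
        if self.a <= 0 or self.A < 1 or not (0 < self.alpha <= 1):
            raise ContractError("require a > 0, A >= 1, 0 < alpha <= 1")

    def gain(self, k: int) -> float:
        return self.a / (self.A + k) ** self.alpha


@dataclass
class IterationRecord:
    k: int
    resolution: int
    value: float
    gradient_max: float
    gain: float
    samples_used: int
    wall_time: float


@dataclass
class IterationLog:
    records: list = field(default_factory=list)

    def append(self, rec: IterationRecord):
        self.records.append(rec)

    def __len__(self):
        return len(self.records)

    def write_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("k\tresolution\tvalue\tgradient_max\tgain\t"
                     "samples_used\twall_time\n")
            for r in self.records:
                fh.write(f"{r.k}\t{r.resolution}\t{r.value:.10g}\t"
                         f"{r.gradient_max:.10g}\t{r.gain:.10g}\t"
                         f"{r.samples_used}\t{r.wall_time:.6f}\n")


@dataclass
class RegistrationConfig:
    """Everything that determines a registration run (deterministic per seed)."""

    resolutions: int = 3
    iterations: int = 200
    metric: str = "msd"
    samples: int = 2000
    stages: tuple = ("similarity", "affine", "bspline")
    final_grid_spacing: float = 6.0   # mm, finest-resolution control spacing
    pyramid_sigma: tuple | None = None    # default: 2^(R-1-l) - 1 per level
    pyramid_factor: tuple | None = None   # default: 2^(R-1-l)
    pyramid_mode: str = "resampler"
    gain: GainSchedule = field(default_factory=GainSchedule)
    seed: int = 0
    partitions: int = 1
    regularizer_weight: float = 0.0
    interpolator: str = "linear"
    histogram_bins: int = 32
    normalize_gradient: bool = True
    tail_average: float = 0.5   # Polyak averaging over this tail fraction
    stage_iterations: dict = field(default_factory=dict)  # kind -> per-res count
    stage_gain: dict = field(default_factory=dict)        # kind -> GainSchedule

    def __post_init__(self):
        if self.resolutions < 1:
            raise ContractError("resolutions must be >= 1")
        if self.iterations < 0:
            raise ContractError("iterations must be >= 0")
        if not (0.0 <= self.tail_average < 1.0):
            raise ContractError("tail_average must be in [0, 1)")
        if self.final_grid_spacing <= 0:
            raise ContractError("final grid spacing must be > 0")
        for s in self.stages:
            if s not in STAGE_KINDS:
                raise ContractError(f"unknown stage kind {s!r}")

    def schedule(self) -> PyramidSchedule:
        R = self.resolutions
        factor = self.pyramid_factor or tuple(2 ** (R - 1 - l) for l in range(R))
        sigma = self.pyramid_sigma or tuple(max(f - 1.0, 0.0) for f in factor)
        return PyramidSchedule(sigma=sigma, factor=factor, mode=self.pyramid_mode)

    def iterations_for(self, stage_kind: str) -> int:
        return int(self.stage_iterations.get(stage_kind, self.iterations))

    def gain_for(self, stage_kind: str) -> GainSchedule:
        return self.stage_gain.get(stage_kind, self.gain)


def gradient_descent_step(mu: np.ndarray, gradient: np.ndarray, gain: float,
                          n_partitions: int = 1) -> np.ndarray:
    """mu - gain * gradient; partition-parallelizable over index ranges.

    With ``n_partitions`` the update is computed over that many disjoint
    contiguous slices — bit-identical to the whole-vector update since the
    operation is purely elementwise.
    """
    mu = np.asarray(mu, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    if mu.shape != gradient.shape:
        raise ContractError("parameter / gradient shape mismatch")
    if gain <= 0:
        raise ContractError("gain must be > 0")
    if not np.all(np.isfinite(gradient)):
        raise NumericalError("non-finite gradient components in update step")
    out = np.empty_like(mu)
    for sl in np.array_split(np.arange(mu.size), max(int(n_partitions), 1)):
        if sl.size:
            s = slice(sl[0], sl[-1] + 1)
            out[s] = mu[s] - gain * gradient[s]
    return out


def _seed_for(config_seed: int, stage: int, resolution: int, k: int) -> int:
    # counter-keyed, reproducible without sequential state
    return (int(config_seed) * 1_000_003 + stage * 10_007 + resolution) & 0x7FFFFFFF


def run_resolution(fixed_level: Image, moving_level: Image,
                   transform: Transform, config: RegistrationConfig,
                   resolution: int, stage_index: int = 0,
                   iterations: int | None = None,
                   gain: GainSchedule | None = None,
                   k_offset: int = 0,
                   mask: LabelImage | None = None):
    """Run the configured iterations at one pyramid level.

    Returns (transform, IterationLog).  A metric overlap failure is retried
    once with a fresh sample set, then aborted.  With ``config.tail_average``
    > 0 the returned parameters are the Polyak-Ruppert average of the iterate
    over that tail fraction of the level's iterations, suppressing the
    random-walk noise floor of constant-direction stochastic steps.
    """
    if iterations is None:
        iterations = config.iterations
    if gain is None:
        gain = config.gain
    log = IterationLog()
    if iterations == 0:
        return transform, log
    moving_interp = make_interpolator(config.interpolator, moving_level)
    fixed_interp = make_interpolator("linear", fixed_level)
    opt = transform.optimized if isinstance(transform, CompositeTransform) \
        else transform
    base_seed = _seed_for(config.seed, stage_index, resolution, 0)
    tail_start = int(np.ceil(iterations * (1.0 - config.tail_average)))
    mu_acc = None
    n_acc = 0
    for k in range(iterations):
        t0 = time.perf_counter()
        report = None
        for attempt in range(2):
            samples = draw_samples(fixed_level, mask, config.samples,
                                   seed=base_seed,
                                   iteration=2 * (k_offset + k) + attempt)
            try:
                report = evaluate_partitioned(
                    config.metric, fixed_level, moving_interp, transform,
                    samples, config.partitions, config.histogram_bins,
                    fixed_interp)
                g = report.derivative
                value = report.value
                if (config.regularizer_weight > 0
                        and isinstance(opt, BSplineTransform)):
                    breg = bending_energy_value_and_derivative(transform, samples)
                    g = g + config.regularizer_weight * breg.derivative
                    value = value + config.regularizer_weight * breg.value
                if np.all(np.isfinite(g)):
                    break
                report = None
            except DegenerateOverlapError:
                report = None
            if attempt == 1:
                raise NumericalError(
                    "metric evaluation failed twice (overlap or non-finite "
                    "derivative)", iteration=k)
        a_k = gain.gain(k_offset + k)
        gmax = float(np.abs(g).max())
        step_gain = a_k / gmax if (config.normalize_gradient and gmax > 0) \
            else a_k
        mu = gradient_descent_step(opt.get_parameters(), g, step_gain)
        opt.set_parameters(mu)
        if k >= tail_start:
            mu_acc = mu.copy() if mu_acc is None else mu_acc + mu
            n_acc += 1
        log.append(IterationRecord(k_offset + k, resolution, value, gmax, a_k,
                                   report.samples_used,
                                   time.perf_counter() - t0))
    if n_acc > 1:
        opt.set_parameters(mu_acc / n_acc)
    return transform, log


# ---------------------------------------------------------------------------
# B-spline grid refinement
# ---------------------------------------------------------------------------

def _dyadic_refine_axis(c: np.ndarray, axis: int) -> np.ndarray:
    """Cubic B-spline subdivision along one axis: spacing halves exactly.

    Fine coefficients (zero-padded coarse sequence c_i, fine index j):
    even j = 2i -> (c_{i-1} + 6 c_i + c_{i+1}) / 8, odd j = 2i+1 ->
    (c_i + c_{i+1}) / 2, for j in [-2, 2n], giving 2n + 3 fine knots whose
    lattice starts one coarse spacing before the coarse origin.
    """
    c = np.moveaxis(c, axis, 0)
    n = c.shape[0]
    pad = np.zeros((2,) + c.shape[1:])
    cp = np.concatenate([pad, c, pad], axis=0)  # index i+2
    out = np.zeros((2 * n + 3,) + c.shape[1:])
    i_even = np.arange(-1, n + 1)  # j = 2i, fine k = j + 2
    out[2 * i_even + 2] = (cp[i_even + 1] + 6.0 * cp[i_even + 2]
                           + cp[i_even + 3]) / 8.0
    i_odd = np.arange(-1, n)       # j = 2i+1, fine k = j + 2
    out[2 * i_odd + 3] = (cp[i_odd + 2] + cp[i_odd + 3]) / 2.0
    return np.moveaxis(out, 0, axis)


def refine_bspline_grid(transform: BSplineTransform,
                        new_spacing) -> BSplineTransform:
    """Transfer to a finer control lattice, preserving the displacement field.

    Exact (to rounding) for dyadic halving via the cubic subdivision weights;
    for any other spacing a least-squares fit of the new coefficients to the
    old displacement field is used and the residual reported on the result as
    ``fit_residual``.
    """
    d = transform.dimension
    new_spacing = np.zeros(d) + np.asarray(new_spacing, dtype=float).reshape(-1)
    if np.any(new_spacing >= transform.grid.spacing):
        raise ContractError("new spacing must be finer than the current grid")
    if np.allclose(new_spacing, transform.grid.spacing / 2.0, rtol=1e-9):
        coeff = transform.coefficients
        for a in range(d):
            coeff = _dyadic_refine_axis(coeff, 1 + a)
        grid = Geometry(coeff.shape[1:],
                        transform.grid.spacing / 2.0,
                        transform.grid.origin - transform.grid.spacing)
        return BSplineTransform(grid, coeff)
    # non-dyadic: least-squares fit on a dense sampling of the support
    low = transform.grid.origin + transform.grid.spacing
    high = (transform.grid.origin
            + (np.asarray(transform.grid.shape) - 2) * transform.grid.spacing)
    grid = bspline_grid_for(low, high, new_spacing)
    fine = BSplineTransform(grid)
    n_side = [max(int(np.ceil((high[a] - low[a]) / new_spacing[a])) * 2 + 1, 4)
              for a in range(d)]
    axes = [np.linspace(low[a], high[a], n_side[a]) for a in range(d)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
    target = transform.map_points(pts) - pts
    w, idx, inside = fine.parameter_weights(pts)
    from scipy.sparse import csr_matrix
    from scipy.sparse.linalg import lsqr
    rows = np.repeat(np.arange(pts.shape[0]), w.shape[1])
    B = csr_matrix((w.reshape(-1), (rows, idx.reshape(-1))),
                   shape=(pts.shape[0], fine.grid_size))
    coeff = np.zeros((d, fine.grid_size))
    residual = 0.0
    for r in range(d):
        sol = lsqr(B, target[:, r], atol=1e-12, btol=1e-12)[0]
        coeff[r] = sol
        residual = max(residual, float(np.max(np.abs(B @ sol - target[:, r]))))
    out = BSplineTransform(grid, coeff.reshape((d,) + tuple(grid.shape)))
    out.fit_residual = residual
    return out


# ---------------------------------------------------------------------------
# full registration driver
# ---------------------------------------------------------------------------

def _initial_stage_transform(kind: str, fixed: Image,
                             config: RegistrationConfig,
                             resolution_levels: int) -> Transform:
    d = fixed.ndim
    center = fixed.geometry.origin + fixed.geometry.direction @ (
        (np.asarray(fixed.shape) - 1) / 2.0 * fixed.geometry.spacing)
    if kind == "translation":
        return TranslationTransform(np.zeros(d))
    if kind == "rigid":
        return RigidTransform(d, center=center)
    if kind == "similarity":
        return SimilarityTransform(d, center=center)
    if kind == "affine":
        return AffineTransform(d, center=center)
    # bspline: coarsest-resolution grid; spacing doubles per remaining level
    spacing0 = config.final_grid_spacing * 2 ** (resolution_levels - 1)
    low, high = fixed.geometry.extent()
    return BSplineTransform(bspline_grid_for(low, high, spacing0))


def register(fixed: Image, moving: Image, config: RegistrationConfig,
             mask: LabelImage | None = None):
    """Full staged multi-resolution registration.

    Returns ``(transform, logs, resampled)`` where ``transform`` is the final
    composite mapping fixed-domain points into the moving domain, ``logs`` is
    a list of per-(stage, resolution) IterationLogs, and ``resampled`` is the
    moving image resampled onto the fixed geometry through the composite.
    Deterministic given ``config.seed`` (bit-exact with one partition).
    """
    if fixed.ndim != moving.ndim:
        raise ContractError("fixed and moving images must share a dimension")
    schedule = config.schedule()
    fixed_levels = build_pyramid(fixed, schedule)
    moving_levels = build_pyramid(moving, schedule)
    R = schedule.levels

    mask_levels = [mask] * R if mask is not None else [None] * R
    if mask is not None and schedule.mode != "off":
        # nearest-propagated mask per level
        mask_levels = []
        for lvl in fixed_levels:
            m = resample(Image(mask.data.astype(np.float64), mask.geometry),
                         TranslationTransform(np.zeros(fixed.ndim)),
                         lvl.geometry, "nearest")
            mask_levels.append(LabelImage(np.rint(m.data).astype(np.int32),
                                          lvl.geometry))

    members = []
    logs = []
    for s_idx, kind in enumerate(config.stages):
        stage_t = _initial_stage_transform(kind, fixed, config, R)
        members.append(stage_t)
        current = CompositeTransform(list(members)) if len(members) > 1 \
            else members[-1]
        iters = config.iterations_for(kind)
        gain = config.gain_for(kind)
        for r in range(R):
            if kind == "bspline" and r > 0:
                refined = refine_bspline_grid(
                    members[-1],
                    config.final_grid_spacing * 2 ** (R - 1 - r))
                members[-1] = refined
                current = CompositeTransform(list(members)) if len(members) > 1 \
                    else members[-1]
            current, log = run_resolution(
                fixed_levels[r], moving_levels[r], current, config,
                resolution=r, stage_index=s_idx, iterations=iters, gain=gain,
                k_offset=r * iters, mask=mask_levels[r])
            logs.append(log)

    final = CompositeTransform(list(members)) if len(members) > 1 else members[-1]
    result = resample(moving, final, fixed.geometry, config.interpolator)
    return final, logs, result
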