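"""Multi-resolution Gaussian pyramid via recursive (IIR) smoothing.

The smoother approximates convolution with the normalized Gaussian
G(x; sigma) by a 4th-order recursive filter in the Deriche family: a causal
and an anti-causal pass per scan line, applied per axis (x, then y, then z).
All scan lines within one axis are independent, so any processing order gives
the identical result; that contract is what makes the per-line work trivially
parallelizable on wide hardware.

Sigma is interpreted in *voxel* units.  Downsampling per level is either
``shrinker`` (take every factor-th voxel, no interpolation) or ``resampler``
(linear interpolation onto a coarser lattice); ``off`` keeps the size.

``max_local_line_length`` is a planning utility for devices that stage each
scan line in a small local memory: with three line-sized float buffers in
16 kB, lines may be at most 1365 elements long.  The implementation here has
no such limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import ContractError, DegenerateInputError
from .image import Geometry, Image

__all__ = [
    "PyramidSchedule",
    "recursive_gaussian_1d",
    "smooth_image",
    "build_pyramid",
    "max_local_line_length",
    "recursive_coefficients",
]

_MODES = ("off", "resampler", "shrinker")

# Deriche's 4th-order approximation of the Gaussian: the impulse response
#   h(x) = (a0 cos(w0 x/s) + a1 sin(w0 x/s)) e^{-b0 x/s}
#        + (c0 cos(w1 x/s) + c1 sin(w1 x/s)) e^{-b1 x/s}
# is a sum of two damped cosinusoids, so the causal and anti-causal passes
# are realized as two *parallel second-order sections* each.  The parallel
# form is markedly better conditioned in single precision than the direct
# 4th-order recursion (pole pairs are parameterized individually).
_A0, _A1 = 1.680, 3.735
_B0, _B1 = 1.783, 1.723
_C0, _C1 = -0.6803, -0.2598
_W0, _W1 = 0.6318, 1.997


def recursive_coefficients(sigma: float):
    """Second-order sections [(num_causal, num_anticausal, den), ...].

    Each damped-cosinusoid term r^n (a cos(n phi) + b sin(n phi)) has the
    exact causal realization (n0 + n1 z^-1) / (1 + d1 z^-1 + d2 z^-2) with
    n0 = a, n1 = r (b sin phi - a cos phi), d1 = -2 r cos phi, d2 = r^2; the
    strictly-anticausal numerator is (n1 - d1 n0) z^-1 - d2 n0 z^-2.  All
    numerators are scaled so the summed filter has unit DC gain, which
    preserves constants exactly in exact arithmetic.
    """
    if sigma <= 0:
        raise ContractError("sigma must be > 0 for recursive coefficients")
    secs = []
    for a, b, alpha, w in ((_A0, _A1, _B0, _W0), (_C0, _C1, _B1, _W1)):
        r = np.exp(-alpha / sigma)
        phi = w / sigma
        n0 = a
        n1 = b * r * np.sin(phi) - a * r * np.cos(phi)
        d1 = -2.0 * r * np.cos(phi)
        d2 = r * r
        secs.append((np.array([n0, n1]),
                     np.array([0.0, n1 - d1 * n0, -d2 * n0]),
                     np.array([1.0, d1, d2])))
    gain = sum((nc.sum() + na.sum()) / den.sum() for nc, na, den in secs)
    return [(nc / gain, na / gain, den) for nc, na, den in secs]


def _pad_width(sigma: float) -> int:
    # long enough that the boundary transient of the IIR passes has died out
    return int(np.ceil(10.0 * sigma)) + 8


def _smooth_along_axis(arr: np.ndarray, sigma: float, axis: int) -> np.ndarray:
    """Recursive Gaussian along one axis of an n-d array (all lines at once)."""
    if sigma == 0:
        return arr
    if arr.shape[axis] < 4:
        raise DegenerateInputError(
            f"axis {axis} has extent {arr.shape[axis]} < 4 with sigma > 0")
    dtype = arr.dtype if arr.dtype in (np.float32, np.float64) else np.float64
    pad = _pad_width(sigma)
    spec = [(0, 0)] * arr.ndim
    spec[axis] = (pad, pad)
    x = np.pad(arr.astype(dtype, copy=False), spec, mode="edge")
    rev = [slice(None)] * arr.ndim
    rev[axis] = slice(None, None, -1)
    rev = tuple(rev)
    y = np.zeros_like(x)
    for num_c, num_a, den in recursive_coefficients(float(sigma)):
        num_c = num_c.astype(dtype)
        num_a = num_a.astype(dtype)
        den = den.astype(dtype)
        y = y + lfilter(num_c, den, x, axis=axis)
        y = y + lfilter(num_a, den, x[rev], axis=axis)[rev]
    crop = [slice(None)] * arr.ndim
    crop[axis] = slice(pad, pad + arr.shape[axis])
    return y[tuple(crop)].astype(dtype, copy=False)


def recursive_gaussian_1d(line: np.ndarray, sigma: float) -> np.ndarray:
    """Causal + anti-causal recursive Gaussian on a single 1-d line.

    ``sigma`` is in samples; sigma = 0 returns the input unchanged.  The
    boundary is initialized by edge-value extension, so constants are
    preserved and mass is approximately conserved for interior-supported
    signals.
    """
    line = np.asarray(line)
    if line.ndim != 1:
        raise ContractError("recursive_gaussian_1d expects a 1-d array")
    if sigma < 0:
        raise ContractError("sigma must be >= 0")
    if sigma == 0:
        return line.copy()
    return _smooth_along_axis(line, float(sigma), axis=0)


def smooth_image(image: Image, sigma) -> Image:
    """Separable recursive Gaussian smoothing, axis passes ordered x, y, z.

    ``sigma`` may be a scalar or per-axis sequence, in voxel units.  Scan
    lines within one axis are mutually independent; the sequential
    implementation and any line order produce the identical result.
    """
    d = image.ndim
    sig = np.zeros(d) + np.asarray(sigma, dtype=float).reshape(-1)
    if sig.size != d:
        raise ContractError(f"sigma must be scalar or length {d}")
    if np.any(sig < 0):
        raise ContractError("sigma must be >= 0")
    arr = image.data
    if np.all(sig == 0):
        return Image(arr.copy(), image.geometry, image.domain_id)
    # filter the deviation from the image mean: the unit-DC filter passes the
    # mean through unchanged, and the smaller magnitudes keep the
    # single-precision accelerated path well conditioned
    m = arr.dtype.type(arr.mean()) if arr.dtype in (np.float32, np.float64) \
        else np.float64(arr.mean())
    arr = arr - m
    for axis in range(d):
        arr = _smooth_along_axis(arr, float(sig[axis]), axis)
    return Image(arr + m, image.geometry, image.domain_id)


@dataclass
class PyramidSchedule:
    """Per-level smoothing scales (voxels) and integer downsampling factors.

    Level ``levels - 1`` is the finest.  The standard 4-level schedule pairs
    factors (8, 4, 2, 1) with sigma (4, 2, 1, 0).
    """

    sigma: tuple = (4.0, 2.0, 1.0, 0.0)
    factor: tuple = (8, 4, 2, 1)
    mode: str = "off"

    def __post_init__(self):
        self.sigma = tuple(np.atleast_1d(s).astype(float) for s in self.sigma)
        self.factor = tuple(int(f) for f in self.factor)
        if len(self.sigma) != len(self.factor):
            raise ContractError("sigma and factor lists must have equal length")
        if any(f < 1 for f in self.factor):
            raise ContractError("factors must be >= 1")
        if any(np.any(s < 0) for s in self.sigma):
            raise ContractError("sigma must be >= 0")
        if self.mode not in _MODES:
            raise ContractError(f"mode must be one of {_MODES}")

    @property
    def levels(self) -> int:
        return len(self.factor)


def _shrink(image: Image, factor: int) -> Image:
    sl = tuple(slice(None, None, factor) for _ in image.shape)
    arr = image.data[sl].copy()
    geom = Geometry(arr.shape, image.spacing * factor, image.origin, image.direction)
    return Image(arr, geom, image.domain_id)


def _linear_resample_to(image: Image, geom: Geometry) -> Image:
    from .interpolators import make_interpolator

    interp = make_interpolator("linear", image)
    pts = geom.grid_points()
    vals = interp.evaluate(pts)
    return Image(vals.reshape(geom.shape).astype(image.data.dtype),
                 geom, image.domain_id)


def build_pyramid(image: Image, schedule: PyramidSchedule) -> list:
    """Smoothed (and optionally downsampled) images, coarsest level first."""
    out = []
    for sig, fac in zip(schedule.sigma, schedule.factor):
        if fac > min(image.shape):
            raise DegenerateInputError(
                f"downsampling factor {fac} exceeds an axis extent {image.shape}")
        level = smooth_image(image, sig) if np.any(np.asarray(sig) > 0) else image
        if schedule.mode == "off" or fac == 1:
            level = Image(level.data.copy(), level.geometry, level.domain_id)
        elif schedule.mode == "shrinker":
            level = _shrink(level, fac)
        else:  # resampler
            new_shape = tuple(int(np.ceil(s / fac)) for s in image.shape)
            geom = Geometry(new_shape, image.spacing * fac, image.origin,
                            image.direction)
            level = _linear_resample_to(level, geom)
        out.append(level)
    return out


def max_local_line_length(local_memory_bytes: int, buffers: int,
                          bytes_per_element: int) -> int:
    """Longest scan line processable with ``buffers`` line-sized element
    buffers in ``local_memory_bytes`` of device-local memory."""
    if local_memory_bytes <= 0 or buffers <= 0 or bytes_per_element <= 0:
        raise ContractError("all inputs must be positive")
    return local_memory_bytes // (buffers * bytes_per_element)
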