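"""Deterministic synthetic test data: images, warped pairs, label atlases.

These generators stand in for acquired scans so the full registration and
cohort pipeline is exercisable without any download.  The intensity model is
a sum of randomly placed anisotropic Gaussian blobs over a smooth intensity
ramp plus optional white noise, clipped to [0, 1000]; the ramp guarantees a
nonzero image gradient everywhere so that nonrigid recovery is identifiable
over the whole domain, not only near blob edges.  Ground-truth warps are
random cubic B-spline fields with a stated control spacing and maximum
displacement; label atlases are Voronoi partitions warped per atlas.

Every generator is bit-deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .image import Geometry, Image, LabelImage
from .resample import resample
from .transforms import (BSplineTransform, Transform, bspline_grid_for,
                         invert_transform)

__all__ = ["FixtureSpec", "make_image", "make_warped_pair", "make_label_atlas"]


@dataclass
class FixtureSpec:
    """Recipe for one deterministic fixture; identical spec -> identical data."""

    shape: tuple = (64, 64, 64)
    spacing: tuple = 1.0
    seed: int = 0
    n_blobs: int | None = None   # default: 20 (2-d) / 80 (3-d), ~40% coverage
    noise_sd: float = 5.0
    ramp_amplitude: float = 150.0
    warp_grid_spacing: float = 16.0   # mm between warp control points
    max_displacement: float = 3.0     # mm, peak ground-truth displacement
    n_regions: int = 8                # Voronoi label count

    def __post_init__(self):
        self.shape = tuple(int(s) for s in np.atleast_1d(self.shape))
        if any(s < 8 for s in self.shape):
            raise ContractError("fixture shape must be >= 8 per axis")
        d = len(self.shape)
        self.spacing = tuple((np.zeros(d) + np.asarray(self.spacing,
                                                       dtype=float)).tolist())
        if self.n_blobs is None:
            # keep the textured fraction of the scene roughly constant
            self.n_blobs = 20 if d == 2 else 80

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.shape, self.spacing)


class _SceneModel:
    """Analytic intensity scene (ramp + Gaussian blobs) defined on all of R^d.

    Being defined beyond the image field of view, the scene can be sampled at
    warped positions outside the lattice — mirroring how a real scanned
    object extends past the acquisition box — so warped pairs carry genuine
    intensity information up to the image boundary.
    """

    def __init__(self, spec: FixtureSpec):
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 11])
        d = len(spec.shape)
        self.size = np.asarray(spec.shape) * np.asarray(spec.spacing)
        direction = rng.normal(size=d)
        self.ramp_direction = direction / np.linalg.norm(direction)
        self.ramp_amplitude = spec.ramp_amplitude
        # blob centers cover a slightly padded box so texture reaches every
        # face of the field of view (the scene continues past the lattice)
        self.centers = rng.uniform(-0.05, 1.05, size=(spec.n_blobs, d)) * self.size
        self.sds = rng.uniform(self.size.min() / 14.0, self.size.min() / 6.0,
                               size=(spec.n_blobs, d))
        self.amps = rng.uniform(150.0, 500.0, size=spec.n_blobs) * rng.choice(
            [-1.0, 1.0], size=spec.n_blobs, p=[0.3, 0.7])

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vals = 200.0 + self.ramp_amplitude * (
            pts @ (self.ramp_direction / self.size))
        for c, s, a in zip(self.centers, self.sds, self.amps):
            q = (((pts - c) / s) ** 2).sum(axis=1)
            vals = vals + a * np.exp(-0.5 * q)
        return np.clip(vals, 0.0, 1000.0)


def make_image(spec: FixtureSpec) -> Image:
    """Smooth blob-sum image with controllable contrast, values in [0, 1000]."""
    geom = spec.geometry
    model = _SceneModel(spec)
    data = model(geom.grid_points()).reshape(geom.shape)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 13])
        data = np.clip(data + rng.normal(0.0, spec.noise_sd, size=geom.shape),
                       0.0, 1000.0)
    return Image(data, geom)


def make_ground_truth_warp(spec: FixtureSpec) -> BSplineTransform:
    """Random cubic B-spline warp with peak displacement ``max_displacement``."""
    geom = spec.geometry
    low, high = geom.extent()
    grid = bspline_grid_for(low, high, spec.warp_grid_spacing)
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 23])
    coeff = rng.normal(0.0, 1.0, size=(geom.ndim,) + tuple(grid.shape))
    warp = BSplineTransform(grid, coeff)
    if spec.max_displacement > 0:
        pts = geom.grid_points()
        disp = warp.map_points(pts) - pts
        peak = np.abs(disp).max()
        warp.coefficients *= spec.max_displacement / max(peak, 1e-12)
    else:
        warp.coefficients[:] = 0.0
    return warp


def make_warped_pair(spec: FixtureSpec):
    """(fixed, moving, true_transform) with known ground truth.

    ``true_transform`` maps fixed-domain points into the moving domain (the
    same direction registration's transform takes), so a successful
    registration of ``moving`` to ``fixed`` recovers its displacement field.
    The moving image samples the analytic scene at inverse-warped positions,
    I_M(y) = scene(T_true^{-1}(y)) (numerical inversion), which makes
    I_M(T_true(x)) = I_F(x) hold by construction everywhere in the fixed
    lattice — including its boundary, since the scene extends beyond the
    field of view.  The moving lattice is padded by the displacement
    amplitude so that every true correspondence lies inside the moving
    field of view (as a scan fully containing the matched anatomy would);
    without that padding a boundary rim of the warp would be unobservable in
    principle.  The peak displacement stays below half the warp grid
    spacing, guaranteeing invertibility; independent noise is added to both
    images.
    """
    if spec.max_displacement >= 0.5 * spec.warp_grid_spacing:
        raise ContractError(
            "max_displacement must stay below half the warp grid spacing")
    fixed = make_image(spec)
    warp = make_ground_truth_warp(spec)
    geom = fixed.geometry
    if spec.max_displacement == 0:
        return fixed, Image(fixed.data.copy(), geom), warp
    pad = int(np.ceil(spec.max_displacement / min(geom.spacing))) + 1
    mov_geom = geom.padded(pad)
    model = _SceneModel(spec)
    inv = invert_transform(warp, geom.padded(pad + 3),
                           tolerance=1e-4, max_iter=200)
    moving_data = model(inv.map_points(mov_geom.grid_points())).reshape(
        mov_geom.shape)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 17])
        moving_data = np.clip(
            moving_data + rng.normal(0.0, spec.noise_sd, size=mov_geom.shape),
            0.0, 1000.0)
    return fixed, Image(moving_data, mov_geom), warp


def make_label_atlas(spec: FixtureSpec, count: int):
    """Synthetic multi-atlas set: Voronoi labels warped per atlas.

    Returns a list of (intensity image, label image) pairs.  Atlas 0 carries
    the unwarped base labeling; the others are resampled through small random
    B-spline warps (peak displacement ``spec.max_displacement``).  With zero
    displacement all atlases are identical.  Labels cover 0..n_regions-1.
    """
    if count < 1:
        raise ContractError("need at least one atlas")
    if spec.n_regions < 2:
        raise ContractError("need at least two regions")
    geom = spec.geometry
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 37])
    size = np.asarray(geom.shape) * np.asarray(geom.spacing)
    seeds = rng.uniform(0.0, 1.0, size=(spec.n_regions, geom.ndim)) * size
    pts = geom.grid_points()
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    base_labels = np.argmin(d2, axis=1).reshape(geom.shape).astype(np.int32)
    base_image = make_image(spec)

    out = []
    for k in range(count):
        if k == 0 or spec.max_displacement == 0:
            out.append((Image(base_image.data.copy(), geom),
                        LabelImage(base_labels.copy(), geom)))
            continue
        sub = FixtureSpec(shape=spec.shape, spacing=spec.spacing,
                          seed=(spec.seed * 101 + k) & 0x7FFFFFFF,
                          warp_grid_spacing=spec.warp_grid_spacing,
                          max_displacement=spec.max_displacement)
        warp = make_ground_truth_warp(sub)
        img = resample(base_image, warp, geom, "linear")
        lab = resample(Image(base_labels.astype(np.float64), geom), warp,
                       geom, "nearest")
        out.append((img, LabelImage(np.rint(lab.data).astype(np.int32), geom)))
    return out
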