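"""Image data model: scalar images with physical geometry, and NIfTI/MetaImage I/O.

A voxel's physical position is the center of the voxel; indices are 0-based.
The mapping from a continuous index ``i`` to a physical point (mm) is

    x = origin + direction @ (spacing * i)

with ``spacing`` strictly positive and ``direction`` an orthonormal d x d
matrix.  The image *domain* is the closed box of voxel centers in continuous
index space, ``0 <= i_k <= shape_k - 1``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import ContractError, CorruptFileError, FormatError

__all__ = [
    "Geometry",
    "Image",
    "LabelImage",
    "voxel_to_world",
    "world_to_voxel",
    "read_image",
    "write_image",
    "read_label_image",
]

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _as_vector(value, d, name):
    out = np.asarray(value, dtype=float).reshape(-1)
    if out.size == 1:
        out = np.full(d, out[0])
    if out.size != d:
        raise ContractError(f"{name} must have length {d}, got {out.size}")
    return out


@dataclass(frozen=True)
class Geometry:
    """Physical-space descriptor of a voxel lattice, without pixel data."""

    shape: tuple
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __init__(self, shape, spacing=1.0, origin=0.0, direction=None):
        shape = tuple(int(s) for s in np.atleast_1d(shape))
        d = len(shape)
        if d not in (2, 3):
            raise ContractError(f"only 2-d and 3-d geometries are supported, got d={d}")
        if any(s < 1 for s in shape):
            raise ContractError(f"shape entries must be >= 1, got {shape}")
        spacing = _as_vector(spacing, d, "spacing")
        if np.any(spacing <= 0):
            raise ContractError(f"spacing must be strictly positive, got {spacing}")
        origin = _as_vector(origin, d, "origin")
        if direction is None:
            direction = np.eye(d)
        direction = np.asarray(direction, dtype=float).reshape(d, d)
        if not np.allclose(direction @ direction.T, np.eye(d), atol=1e-6):
            raise ContractError("direction matrix must be orthonormal within 1e-6")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)
        self.spacing.setflags(write=False)
        self.origin.setflags(write=False)
        self.direction.setflags(write=False)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def voxel_volume(self) -> float:
        """Volume (mm^d) of one voxel."""
        return float(np.prod(self.spacing))

    def __eq__(self, other):
        return (
            isinstance(other, Geometry)
            and self.shape == other.shape
            and np.array_equal(self.spacing, other.spacing)
            and np.array_equal(self.origin, other.origin)
            and np.array_equal(self.direction, other.direction)
        )

    def __hash__(self):
        return hash((self.shape, self.spacing.tobytes(), self.origin.tobytes(),
                     self.direction.tobytes()))

    def close_to(self, other: "Geometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape (n_voxels, d), C order."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s, dtype=float) for s in self.shape], indexing="ij"),
            axis=-1,
        ).reshape(-1, self.ndim)
        return voxel_to_world(self, idx)

    def padded(self, voxels: int) -> "Geometry":
        """Geometry grown by ``voxels`` lattice points on every side."""
        voxels = int(voxels)
        shape = tuple(s + 2 * voxels for s in self.shape)
        origin = self.origin - self.direction @ (self.spacing * voxels)
        return Geometry(shape, self.spacing, origin, self.direction)

    def extent(self):
        """(low, high) physical corners of the closed box of voxel centers."""
        corners_idx = np.stack(
            np.meshgrid(*[(0.0, s - 1.0) for s in self.shape], indexing="ij"), axis=-1
        ).reshape(-1, self.ndim)
        corners = voxel_to_world(self, corners_idx)
        return corners.min(axis=0), corners.max(axis=0)


def voxel_to_world(geometry: Geometry, index) -> np.ndarray:
    """Map continuous voxel indices to physical points (mm).

    ``index`` may be a single length-d index or an (n, d) array.
    """
    idx = np.asarray(index, dtype=float)
    single = idx.ndim == 1
    idx = np.atleast_2d(idx)
    pts = geometry.origin + (geometry.spacing * idx) @ geometry.direction.T
    return pts[0] if single else pts


def world_to_voxel(geometry: Geometry, point) -> np.ndarray:
    """Exact inverse of :func:`voxel_to_world`."""
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    idx = ((pts - geometry.origin) @ geometry.direction) / geometry.spacing
    return idx[0] if single else idx


@dataclass
class Image:
    """A d-dimensional scalar image together with its physical geometry.

    ``domain_id`` is an opaque tag naming the space the image lives in
    (e.g. the fixed domain or a moving domain).
    """

    data: np.ndarray
    geometry: Geometry
    domain_id: str = ""

    _allowed_dtypes = (np.float32, np.float64)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype not in self._allowed_dtypes:
            self.data = self.data.astype(np.float64)
        if np.isnan(self.data).any():
            raise ContractError("image data must not contain NaN")
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ContractError(
                f"data shape {self.data.shape} does not match geometry shape "
                f"{self.geometry.shape}"
            )

    # convenience pass-throughs
    @property
    def shape(self):
        return self.geometry.shape

    @property
    def ndim(self):
        return self.geometry.ndim

    @property
    def spacing(self):
        return self.geometry.spacing

    @property
    def origin(self):
        return self.geometry.origin

    @property
    def direction(self):
        return self.geometry.direction

    def astype(self, dtype) -> "Image":
        """Precision cast (e.g. the single-precision accelerated storage path)."""
        return Image(self.data.astype(dtype), self.geometry, self.domain_id)


@dataclass
class LabelImage(Image):
    """Integer region labels >= 0 on a voxel lattice; background is label 0."""

    _allowed_dtypes = (np.int8, np.int16, np.int32, np.int64,
                       np.uint8, np.uint16, np.uint32, np.uint64)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=0):
                raise ContractError("label data must be integer-valued")
            self.data = rounded.astype(np.int32)
        if self.data.min(initial=0) < 0:
            raise ContractError("labels must be >= 0")
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ContractError("label data shape does not match geometry")

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the image."""
        u = np.unique(self.data)
        return u[u > 0]


# ---------------------------------------------------------------------------
# File I/O (SimpleITK behind the scenes; NIfTI-1 and MetaImage only)
# ---------------------------------------------------------------------------

def _check_extension(path: str) -> None:
    p = str(path).lower()
    if not p.endswith(_EXTENSIONS):
        raise FormatError(
            f"unsupported image format for {path!r}; expected one of {_EXTENSIONS}"
        )


def _sitk_to_geometry(img: sitk.Image) -> Geometry:
    d = img.GetDimension()
    shape = tuple(img.GetSize())
    spacing = np.array(img.GetSpacing())
    origin = np.array(img.GetOrigin())
    direction = np.array(img.GetDirection()).reshape(d, d)
    return Geometry(shape, spacing, origin, direction)


def read_image(path) -> Image:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar image.

    The in-memory array axis order matches the on-disk physical axis order:
    axis k of ``data`` carries ``spacing[k]``.  NIfTI orientation comes from
    the sform (qform fallback, handled by the reader); MetaImage's
    TransformMatrix maps directly onto ``direction``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    _check_extension(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - reader-specific messages
        raise CorruptFileError(f"cannot read {path!r}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # axes reversed wrt sitk indexing
    arr = np.transpose(arr)
    geom = _sitk_to_geometry(img)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64)
    return Image(np.ascontiguousarray(arr), geom)


def read_label_image(path) -> LabelImage:
    img = read_image(path)
    return LabelImage(np.rint(img.data).astype(np.int32), img.geometry)


def _to_sitk(image: Image) -> sitk.Image:
    arr = np.transpose(image.data)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(float(s) for s in image.spacing))
    img.SetOrigin(tuple(float(o) for o in image.origin))
    img.SetDirection(tuple(float(v) for v in image.direction.reshape(-1)))
    return img


def write_image(image: Image, path) -> None:
    """Write to NIfTI or MetaImage; format chosen by the path extension.

    MetaImage (.mha/.mhd) uses raw storage, so arrays round-trip bit-exactly.
    """
    _check_extension(path)
    sitk.WriteImage(_to_sitk(image), str(path))


def write_vector_field(field: np.ndarray, geometry: Geometry, path) -> None:
    """Write a displacement field (shape ``geometry.shape + (d,)``) as a
    vector-valued MetaImage/NIfTI."""
    _check_extension(path)
    d = geometry.ndim
    if field.shape != tuple(geometry.shape) + (d,):
        raise ContractError("field shape must be geometry.shape + (d,)")
    arr = np.transpose(field, tuple(range(d - 1, -1, -1)) + (d,))
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=True)
    img.SetSpacing(tuple(float(s) for s in geometry.spacing))
    img.SetOrigin(tuple(float(o) for o in geometry.origin))
    img.SetDirection(tuple(float(v) for v in geometry.direction.reshape(-1)))
    sitk.WriteImage(img, str(path))


def read_vector_field(path):
    """Read a vector field written by :func:`write_vector_field`.

    Returns ``(field, geometry)`` with field shape ``geometry.shape + (d,)``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    d = img.GetDimension()
    arr = sitk.GetArrayFromImage(img)
    arr = np.transpose(arr, tuple(range(d - 1, -1, -1)) + (d,))
    geom = _sitk_to_geometry(img)
    return np.ascontiguousarray(arr.astype(np.float64)), geom
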