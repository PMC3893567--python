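"""Cohort-level operations: unbiased template construction, multi-atlas label
fusion, modulated feature extraction, and comparison measures.

Template space is built without bias toward any subject by averaging the
pairwise transformations from one subject to all others (the subject's own
identity transformation included),

    U_i(x) = (1/N) sum_j W_{i,j}(x),      V_i = U_i^{-1},

so V_i maps template-space points into subject i's space.  The template
image is the voxelwise mean of the subjects resampled through their V_i.
Propagated atlas labels are fused by majority vote.  Warped probabilistic
tissue maps are modulated — multiplied by the Jacobian determinant of the
deformation — so that integrated tissue volume is preserved by the spatial
normalization; region-wise volume features divide the per-ROI tissue volume
by intracranial volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateInputError
from .image import Geometry, Image, LabelImage
from .resample import resample
from .transforms import (Transform, TranslationTransform, average_transforms,
                         displacement_field, invert_transform)

__all__ = [
    "TransformGraph",
    "FeatureTable",
    "build_template_transform",
    "build_template_image",
    "majority_vote_fusion",
    "modulate",
    "region_volume_features",
    "nrmse",
    "field_rmse",
    "dice",
    "zscore_features",
]


@dataclass
class TransformGraph:
    """Pairwise transforms W[i, j] from subject i's space to subject j's.

    ``pairwise`` maps ordered (i, j) pairs of subject identifiers to
    transforms; the diagonal W[i, i] is the identity and may be omitted (it
    is supplied implicitly during averaging).
    """

    subjects: list
    pairwise: dict

    def transforms_from(self, subject):
        """All W[subject, j] for j != subject, in subject order."""
        out = []
        for j in self.subjects:
            if j == subject:
                continue
            key = (subject, j)
            if key not in self.pairwise:
                raise ContractError(f"missing pairwise transform {key}")
            out.append(self.pairwise[key])
        return out


def build_template_transform(graph: TransformGraph, subject, geometry: Geometry,
                             tolerance: float = 0.01, max_iter: int = 50):
    """(U_i, V_i) for one subject: transformation average and its inverse.

    U_i averages W_{i,j} over all subjects j with the identity W_{i,i}
    included; V_i inverts U_i by damped fixed-point iteration on ``geometry``.
    The average is sampled on a lattice padded by the displacement amplitude
    so the inverse stays well defined at the domain edge.  The achieved
    inversion residual is available as ``V_i.max_residual``.
    """
    others = graph.transforms_from(subject)
    u = average_transforms(others, geometry, include_identity=True)
    peak = float(np.abs(u.field).max())
    pad = int(np.ceil(peak / float(np.min(geometry.spacing)))) + 1
    if pad > 0:
        u = average_transforms(others, geometry.padded(pad),
                               include_identity=True)
    v = invert_transform(u, geometry, tolerance=tolerance, max_iter=max_iter)
    return u, v


def build_template_image(images, transforms, geometry: Geometry) -> Image:
    """Voxelwise mean of each image resampled through its V_i onto geometry."""
    images = list(images)
    transforms = list(transforms)
    if len(images) != len(transforms):
        raise ContractError("one transform per image is required")
    if not images:
        raise ContractError("need at least one image")
    acc = np.zeros(geometry.shape)
    for img, v in zip(images, transforms):
        acc += resample(img, v, geometry, "linear").data
    return Image(acc / len(images), geometry)


def majority_vote_fusion(propagated_labels) -> LabelImage:
    """Per-voxel most frequent label; ties break to the smallest label value.

    Atlas order cannot influence the result (counts are order-free and the
    tie rule is value-based).
    """
    labels = list(propagated_labels)
    if not labels:
        raise ContractError("need at least one label image")
    geom = labels[0].geometry
    for l in labels[1:]:
        if not l.geometry.close_to(geom):
            raise ContractError("label images must share a geometry")
    max_label = int(max(int(l.data.max()) for l in labels))
    counts = np.zeros((max_label + 1,) + tuple(geom.shape), dtype=np.int32)
    for l in labels:
        for v in np.unique(l.data):
            counts[int(v)] += (l.data == v)
    fused = np.argmax(counts, axis=0).astype(np.int32)  # first max = smallest
    return LabelImage(fused, geom)


def modulate(map_image: Image, transform: Transform) -> Image:
    """Multiply a warped probabilistic map by the transform's Jacobian
    determinant, voxel by voxel on the map's (template) lattice.

    ``transform`` is the map that was used to pull the image into template
    space (template point -> subject point); modulation by its determinant
    makes the integrated map mass invariant to the warp, so total tissue
    volume is unchanged by spatial normalization.  Negative determinants
    (folding) trigger a warning carrying their count.
    """
    geom = map_image.geometry
    pts = geom.grid_points()
    jac = transform.spatial_jacobian_batch(pts)
    det = np.linalg.det(jac).reshape(geom.shape)
    n_neg = int((det < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} voxels have negative Jacobian determinant "
                      "(folding)", RuntimeWarning, stacklevel=2)
    return Image(map_image.data * det, geom, map_image.domain_id)


def region_volume_features(gm_map: Image, labels: LabelImage, icv: float,
                           roi_labels=None, exclude=()) -> np.ndarray:
    """Per-ROI tissue volume fraction: sum of the probabilistic map over the
    ROI times the voxel volume, divided by intracranial volume (mm^3).

    ``roi_labels`` defaults to the sorted nonzero labels present; labels in
    ``exclude`` are dropped.  A requested label absent from the label image
    yields feature 0 with a warning.
    """
    if icv <= 0:
        raise ContractError("intracranial volume must be > 0")
    if not gm_map.geometry.close_to(labels.geometry):
        raise ContractError("map and labels must share a geometry")
    if roi_labels is None:
        roi_labels = [int(l) for l in labels.labels() if int(l) not in set(exclude)]
    else:
        roi_labels = [int(l) for l in roi_labels if int(l) not in set(exclude)]
    voxvol = gm_map.geometry.voxel_volume
    present = set(int(v) for v in np.unique(labels.data))
    out = np.zeros(len(roi_labels))
    for i, lab in enumerate(roi_labels):
        if lab not in present:
            warnings.warn(f"label {lab} absent from label image",
                          RuntimeWarning, stacklevel=2)
            continue
        out[i] = float(gm_map.data[labels.data == lab].sum()) * voxvol / icv
    return out


def nrmse(reference: Image, test: Image) -> float:
    """Normalized root mean square error,
    sqrt( sum (I_ref - I_test)^2 / sum I_ref^2 )."""
    a = np.asarray(reference.data, dtype=np.float64)
    b = np.asarray(test.data, dtype=np.float64)
    if a.shape != b.shape:
        raise ContractError("images must have identical shapes")
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise DegenerateInputError("nRMSE undefined for an all-zero reference")
    return float(np.sqrt(np.sum((a - b) ** 2) / denom))


def field_rmse(field_a, field_b, mask: LabelImage | None = None) -> float:
    """Root-mean-square Euclidean difference (mm) between displacement fields.

    Fields are arrays of shape ``shape + (d,)`` (e.g. from
    :func:`voxelreg.transforms.displacement_field`); with a mask only voxels
    with nonzero mask value contribute.
    """
    a = np.asarray(field_a, dtype=np.float64)
    b = np.asarray(field_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ContractError("fields must have identical shapes")
    diff2 = np.sum((a - b) ** 2, axis=-1)
    if mask is not None:
        keep = mask.data > 0
        if keep.shape != diff2.shape:
            raise ContractError("mask shape does not match the fields")
        if not keep.any():
            raise DegenerateInputError("mask has no nonzero voxels")
        diff2 = diff2[keep]
    return float(np.sqrt(diff2.mean()))


def dice(labels_a: LabelImage, labels_b: LabelImage, label: int) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of one label; both empty -> 1."""
    if not labels_a.geometry.close_to(labels_b.geometry):
        raise ContractError("label images must share a geometry")
    a = labels_a.data == label
    b = labels_b.data == label
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0  # perfect agreement of absence
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass
class FeatureTable:
    """Subjects x features matrix with a normalization state flag."""

    subjects: list
    feature_names: list
    values: np.ndarray
    normalization: str = "raw"  # raw | z-scored

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.subjects), len(self.feature_names)):
            raise ContractError("values must be (n_subjects, n_features)")

    def write_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("subject\t" + "\t".join(map(str, self.feature_names)) + "\n")
            for s, row in zip(self.subjects, self.values):
                fh.write(str(s) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def zscore_features(table: FeatureTable, fit_rows=None) -> FeatureTable:
    """Normalize columns to zero mean, unit variance (population sd, fitted on
    ``fit_rows``, applied to all rows).

    Columns constant on the fit rows become zero with a warning.  Idempotent
    on already-normalized input (up to rounding).
    """
    if fit_rows is None:
        fit_idx = np.arange(len(table.subjects))
    else:
        lookup = {s: i for i, s in enumerate(table.subjects)}
        fit_idx = np.array([lookup[s] for s in fit_rows])
    if fit_idx.size < 2:
        raise ContractError("need at least two fit rows")
    sub = table.values[fit_idx]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0)  # population convention (divide by n)
    out = np.zeros_like(table.values)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} constant feature column(s) set to 0",
                      RuntimeWarning, stacklevel=2)
    out[:, ok] = (table.values[:, ok] - mean[ok]) / sd[ok]
    return FeatureTable(list(table.subjects), list(table.feature_names), out,
                        normalization="z-scored")
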