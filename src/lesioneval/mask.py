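"""Voxel-grid data model and metric (millimetre-based) morphology.

Everything downstream — lesion typing, accuracy metrics, threshold
optimization — operates on the two containers defined here:

* :class:`BinaryMask3D`: a boolean voxel grid with physical spacing in mm.
* :class:`LesionLabelMap`: connected components labelled 1..n with a
  per-lesion record (voxel count, volume in ml, anatomical location).

All spatial computation happens in voxel space; the affine is carried
through I/O untouched and never enters any metric. Spherical structuring
elements are specified by a physical radius in mm and converted per axis
by the voxel spacing, so a "1 mm kernel" behaves sensibly on anisotropic
grids (e.g. 0.98 x 0.98 x 1.2 mm FLAIR).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "BinaryMask3D",
    "LesionRecord",
    "LesionLabelMap",
    "read_mask",
    "write_mask",
    "connected_components",
    "filter_min_cluster",
    "spherical_offsets",
    "ball_structure",
    "dilate",
    "erode",
    "write_labelmap",
]

#: Allowed anatomical location classes for a lesion.
LOCATIONS = ("periventricular", "juxtacortical", "infratentorial", "deep", "other")
UNCLASSIFIED = "unclassified"

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing}")
    return spacing


@dataclass(frozen=True)
class BinaryMask3D:
    """A 3D boolean voxel grid with edge lengths in mm.

    Index order is fixed as (i, j, k); world coordinates are never used
    in computation.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {data.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_ml

    def check_compatible(self, other: "BinaryMask3D | LesionLabelMap") -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")


@dataclass
class LesionRecord:
    """Per-lesion bookkeeping: size, physical volume, anatomical class."""

    lesion_id: int
    n_voxels: int
    volume_ml: float
    location: str = UNCLASSIFIED

    def __post_init__(self):
        if self.lesion_id < 1:
            raise ValueError("lesion_id must be a positive integer")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be positive")


@dataclass
class LesionLabelMap:
    """Connected components labelled contiguously from 1, with records.

    Label 0 is background. Components are numbered in lexicographic order
    of their minimum (i, j, k) voxel so outputs are bit-reproducible.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    records: list[LesionRecord] = field(default_factory=list)
    affine: np.ndarray | None = None

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int32)
        self.labels = labels
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_lesions(self) -> int:
        return len(self.records)

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def total_volume_ml(self) -> float:
        return float(sum(r.volume_ml for r in self.records))

    @property
    def lesion_ids(self) -> list[int]:
        return [r.lesion_id for r in self.records]

    def as_binary(self) -> BinaryMask3D:
        return BinaryMask3D(self.labels > 0, self.spacing, self.affine)

    def lesion_mask(self, lesion_id: int) -> np.ndarray:
        return self.labels == lesion_id

    def record(self, lesion_id: int) -> LesionRecord:
        for r in self.records:
            if r.lesion_id == lesion_id:
                return r
        raise KeyError(f"no lesion with id {lesion_id}")

    def check_compatible(self, other: "BinaryMask3D | LesionLabelMap") -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in header: {spacing}")
    return spacing


def _load_3d(path) -> tuple[np.ndarray, tuple, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return data, _spacing_from_header(img), img.affine


def read_mask(path, binarize_threshold: float = 0.0) -> BinaryMask3D:
    """Read a NIfTI volume as a binary mask.

    Voxels strictly above ``binarize_threshold`` become foreground; a
    probability of exactly 0.5 at the default LST threshold is therefore
    reproducibly excluded.
    """
    data, spacing, affine = _load_3d(path)
    return BinaryMask3D(data > binarize_threshold, spacing, affine)


def write_mask(mask: BinaryMask3D, path) -> None:
    affine = mask.affine
    if affine is None:
        affine = np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_probability_volume(path) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Read a NIfTI volume as a float array, returning (data, spacing, affine)."""
    data, spacing, affine = _load_3d(path)
    return np.asarray(data, dtype=float), spacing, affine


def write_labelmap(labelmap: LesionLabelMap, path, sidecar_csv=None) -> None:
    """Write an integer NIfTI plus an optional sidecar CSV of lesion records."""
    affine = labelmap.affine
    if affine is None:
        affine = np.diag([*labelmap.spacing, 1.0])
    img = nib.Nifti1Image(labelmap.labels.astype(np.int32), affine)
    img.header.set_zooms(labelmap.spacing)
    nib.save(img, str(path))
    if sidecar_csv is not None:
        with open(sidecar_csv, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["lesion_id", "n_voxels", "volume_ml", "location"])
            for r in labelmap.records:
                w.writerow([r.lesion_id, r.n_voxels, f"{r.volume_ml:.6f}", r.location])


def read_labelmap(path, sidecar_csv=None) -> LesionLabelMap:
    data, spacing, affine = _load_3d(path)
    labels = np.rint(data).astype(np.int32)
    records = []
    if sidecar_csv is not None:
        with open(sidecar_csv, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    LesionRecord(
                        lesion_id=int(row["lesion_id"]),
                        n_voxels=int(row["n_voxels"]),
                        volume_ml=float(row["volume_ml"]),
                        location=row["location"],
                    )
                )
    else:
        records = _records_from_labels(labels, spacing)
    return LesionLabelMap(labels, spacing, records, affine)


# ---------------------------------------------------------------------------
# Connected components and cluster-size filtering


def _records_from_labels(labels: np.ndarray, spacing) -> list[LesionRecord]:
    vox_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return [
        LesionRecord(int(i), int(c), float(c) * vox_ml)
        for i, c in zip(ids, counts)
    ]


def connected_components(mask: BinaryMask3D, connectivity: int = 26) -> LesionLabelMap:
    """Label connected components of a binary mask.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (faces, edges
    and corners — the default used for lesion counting). Components are
    relabelled 1..n in lexicographic order of their minimum (i, j, k)
    voxel, making the labelling deterministic.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        return LesionLabelMap(
            np.zeros(mask.shape, dtype=np.int32), mask.spacing, [], mask.affine
        )
    # first occurrence in C-order raveled array == lexicographic minimum voxel
    flat = raw.ravel()
    ids, first = np.unique(flat, return_index=True)
    keep = ids > 0
    order = np.argsort(first[keep])
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[ids[keep][order]] = np.arange(1, keep.sum() + 1)
    labels = remap[raw]
    return LesionLabelMap(
        labels, mask.spacing, _records_from_labels(labels, mask.spacing), mask.affine
    )


def filter_min_cluster(labelmap: LesionLabelMap, min_voxels: int) -> LesionLabelMap:
    """Remove components smaller than ``min_voxels``; relabel contiguously.

    The boundary is inclusive: a component of exactly ``min_voxels``
    voxels survives. Surviving components keep their relative order.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    survivors = [r for r in labelmap.records if r.n_voxels >= min_voxels]
    max_label = max((r.lesion_id for r in labelmap.records), default=0)
    remap = np.zeros(max_label + 1, dtype=np.int32)
    new_records = []
    for new_id, r in enumerate(survivors, start=1):
        remap[r.lesion_id] = new_id
        new_records.append(replace(r, lesion_id=new_id))
    labels = remap[labelmap.labels]
    return LesionLabelMap(labels, labelmap.spacing, new_records, labelmap.affine)


# ---------------------------------------------------------------------------
# Metric morphology


def spherical_offsets(radius_mm: float, spacing=(1.0, 1.0, 1.0)) -> set[tuple[int, int, int]]:
    """Integer voxel offsets within a physical radius (inclusive).

    Returns every (a, b, c) with sqrt((a*dx)^2 + (b*dy)^2 + (c*dz)^2)
    <= radius_mm. Always contains (0, 0, 0).
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be non-negative")
    spacing = _check_spacing(spacing)
    reach = [int(np.floor(radius_mm / s)) for s in spacing]
    offs = set()
    for a in range(-reach[0], reach[0] + 1):
        for b in range(-reach[1], reach[1] + 1):
            for c in range(-reach[2], reach[2] + 1):
                d2 = (a * spacing[0]) ** 2 + (b * spacing[1]) ** 2 + (c * spacing[2]) ** 2
                if d2 <= radius_mm**2 + 1e-12:
                    offs.add((a, b, c))
    return offs


def ball_structure(radius_mm: float, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Boolean structuring element for :func:`dilate` / :func:`erode`."""
    offs = spherical_offsets(radius_mm, spacing)
    reach = [max(abs(o[ax]) for o in offs) for ax in range(3)]
    st = np.zeros([2 * r + 1 for r in reach], dtype=bool)
    for a, b, c in offs:
        st[a + reach[0], b + reach[1], c + reach[2]] = True
    return st


def dilate(mask: BinaryMask3D, radius_mm: float) -> BinaryMask3D:
    """Minkowski dilation with a spherical kernel given in mm."""
    if radius_mm == 0:
        return mask
    st = ball_structure(radius_mm, mask.spacing)
    out = ndimage.binary_dilation(mask.data, structure=st)
    return BinaryMask3D(out, mask.spacing, mask.affine)


def erode(mask: BinaryMask3D, radius_mm: float) -> BinaryMask3D:
    """Minkowski erosion; out-of-bounds neighbours are background."""
    if radius_mm == 0:
        return mask
    st = ball_structure(radius_mm, mask.spacing)
    out = ndimage.binary_erosion(mask.data, structure=st, border_value=0)
    return BinaryMask3D(out, mask.spacing, mask.affine)
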