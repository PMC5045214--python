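"""Integer-labelled volumetric parcellations.

An atlas assigns every brain voxel to exactly one region of interest
(ROI).  Real studies use anatomical parcellations such as the 116-region
AAL atlas; for synthetic cohorts we build a contiguous block parcellation
of the same cardinality so that every downstream regional computation
(regional means, ROI time series, connectivity) has the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AtlasParcellation:
    """A 3-D integer label volume defining N regions of interest.

    Label 0 is reserved for background; every value in ``roi_ids`` is a
    positive integer occurring at least once in ``labels``.
    """

    labels: np.ndarray
    roi_ids: tuple[int, ...]
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D integer array")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        ids = tuple(int(i) for i in self.roi_ids)
        if any(i <= 0 for i in ids):
            raise ValueError("roi_ids must be positive (0 is background)")
        if list(ids) != sorted(ids):
            raise ValueError("roi_ids must be sorted ascending")
        present = set(np.unique(labels).tolist()) - {0}
        missing = set(ids) - present
        if missing:
            raise ValueError(f"roi_ids absent from label volume: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "roi_ids", ids)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def roi_mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


def _kd_split(labels: np.ndarray, origin: tuple[int, int, int],
              box: tuple[int, int, int], k: int, first_label: int) -> None:
    """Recursively split a box into k compact sub-boxes of ~equal volume."""
    if k == 1:
        sl = tuple(slice(o, o + s) for o, s in zip(origin, box))
        labels[sl] = first_label
        return
    k1 = k // 2
    k2 = k - k1
    axis = int(np.argmax(box))
    n = box[axis]
    area = int(np.prod(box)) // n
    p = int(round(n * k1 / k))
    p = min(max(p, 1), n - 1)
    # each side must be able to host its share of (non-empty) regions
    while p * area < k1:
        p += 1
    while (n - p) * area < k2:
        p -= 1
    left_box = tuple(p if a == axis else s for a, s in enumerate(box))
    right_box = tuple(n - p if a == axis else s for a, s in enumerate(box))
    right_origin = tuple(o + p if a == axis else o for a, o in enumerate(origin))
    _kd_split(labels, origin, left_box, k1, first_label)
    _kd_split(labels, right_origin, right_box, k2, first_label + k1)


def make_atlas(volume_shape: tuple[int, int, int], n_rois: int) -> AtlasParcellation:
    """Partition a volume into ``n_rois`` compact, near-equal box regions.

    The volume is split recursively along its longest axis (a k-d-tree
    decomposition) with region counts allocated proportionally, so every
    ROI is a contiguous rectangular block, volumes agree up to plane
    rounding, and regions are spatially compact -- the shape regime a
    local-neighbourhood statistic such as regional homogeneity assumes.
    Labels run 1..n_rois; the whole volume is treated as brain, which is
    the appropriate stand-in when the simulated volume is itself the
    brain mask.

    Raises
    ------
    ValueError
        If ``n_rois`` exceeds the number of voxels.
    """
    shape = tuple(int(s) for s in volume_shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"volume_shape must be 3 positive integers, got {volume_shape}")
    n_vox = int(np.prod(shape))
    n_rois = int(n_rois)
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if n_rois > n_vox:
        raise ValueError(f"n_rois={n_rois} exceeds voxel count {n_vox}")
    labels = np.zeros(shape, dtype=np.int32)
    _kd_split(labels, (0, 0, 0), shape, n_rois, 1)
    return AtlasParcellation(labels=labels, roi_ids=tuple(range(1, n_rois + 1)))


def interior_roi_ids(atlas: AtlasParcellation) -> list[int]:
    """ROIs that contain at least one voxel with a full 3x3x3 in-volume
    neighbourhood (i.e. ROIs that survive boundary-excluding local
    statistics such as regional homogeneity)."""
    interior = np.zeros(atlas.shape, dtype=bool)
    if all(s >= 3 for s in atlas.shape):
        interior[1:-1, 1:-1, 1:-1] = True
    out = []
    for rid in atlas.roi_ids:
        if np.any(interior & atlas.roi_mask(rid)):
            out.append(rid)
    return out
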