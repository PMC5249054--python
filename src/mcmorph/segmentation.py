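"""Extraction of labelled calcification objects from grayscale volumes.

Foreground uses 26-connectivity (full 3x3x3 neighbourhood) so that thin,
diagonal, linear calcifications are not fragmented; labels are assigned in
(z, y, x) raster-scan order of each component's first voxel, which makes the
labelling deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import VoxelVolume

logger = logging.getLogger(__name__)

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LabeledVolume:
    """Integer label grid: 0 is background, objects are labelled 1..n_objects."""

    labels: np.ndarray
    spacing: float
    n_objects: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")

    def object_mask(self, label: int) -> np.ndarray:
        if not 1 <= label <= self.n_objects:
            raise ValueError(f"label {label} outside 1..{self.n_objects}")
        return self.labels == label

    def voxel_counts(self) -> np.ndarray:
        """Voxel count per label, index 0 holding the background count."""
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)


def threshold_volume(
    volume: VoxelVolume,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> VoxelVolume:
    """Binarize a grayscale volume; the mask is True where intensity >= t.

    ``method`` is ``"otsu"`` (threshold maximizing between-class variance) or
    ``"fixed"`` (requires ``fixed_value``).  The chosen threshold is logged so
    the segmentation is auditable.
    """
    data = volume.astype_float()
    if method == "otsu":
        if fixed_value is not None:
            raise ValueError("fixed_value is only valid with method='fixed'")
        if np.ptp(data) == 0:
            raise ValueError(
                "constant-intensity volume: Otsu thresholding has no classes to separate"
            )
        threshold = float(threshold_otsu(data))
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        threshold = float(fixed_value)
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    logger.info("threshold_volume: method=%s threshold=%.6g", method, threshold)
    return VoxelVolume(
        data=data >= threshold, spacing=volume.spacing, origin=volume.origin
    )


def label_components(mask: VoxelVolume, connectivity: int = 26) -> LabeledVolume:
    """Label 26-connected foreground components.

    scipy's raster-scan labelling guarantees labels are ordered by each
    component's first-encountered voxel in (z, y, x) scan order.
    """
    if connectivity != 26:
        raise ValueError("only 26-connectivity is supported for foreground")
    data = np.asarray(mask.data)
    if data.dtype != bool:
        raise ValueError("mask must be boolean; run threshold_volume first")
    labels, n = ndimage.label(data, structure=_STRUCTURE_26)
    return LabeledVolume(labels=labels, spacing=mask.spacing, n_objects=int(n))


def filter_objects(labeled: LabeledVolume, min_voxels: int = 1) -> LabeledVolume:
    """Drop objects smaller than ``min_voxels`` voxels; relabel to 1..n.

    The cutoff removes objects *strictly smaller* than ``min_voxels``, so
    ``min_voxels=3`` keeps 3-voxel objects.  Surviving labels keep their
    relative order.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if min_voxels == 1 or labeled.n_objects == 0:
        return labeled
    counts = labeled.voxel_counts()
    keep = np.flatnonzero(counts[1:] >= min_voxels) + 1
    lut = np.zeros(labeled.n_objects + 1, dtype=labeled.labels.dtype)
    lut[keep] = np.arange(1, len(keep) + 1)
    return LabeledVolume(
        labels=lut[labeled.labels], spacing=labeled.spacing, n_objects=len(keep)
    )
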