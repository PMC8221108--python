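"""Surface reconstruction: background subtraction, labeling, filtering.

Mirrors the standard "surfaces" workflow for cleared-tissue stacks:

1. estimate a smooth background (large-scale Gaussian) and subtract it,
2. threshold the residual and label 3-D connected components,
3. drop components outside a voxel-count window — sub-resolution specks
   below, neuron-scale bodies above — leaving the cell population,
4. estimate total tissue volume from the autofluorescence envelope by
   absolute intensity thresholding of the raw stack.

Touching cells merge into one component; no watershed splitting is
attempted (documented limitation — scenes are expected to be sparse at
the densities this pipeline targets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import ImageStack

__all__ = [
    "SegmentationParams",
    "LabeledVolume",
    "NoTissueError",
    "subtract_background",
    "segment_cells",
    "filter_by_voxels",
    "tissue_volume",
]


class NoTissueError(RuntimeError):
    """Raised when no voxel clears the tissue threshold."""


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation stage.

    background_sigma : µm
        Scale of the Gaussian background estimator; must be much larger
        than a cell so cells survive subtraction.
    cell_threshold : intensity units
        Foreground cut on the background-subtracted stack.
    min_voxels, max_voxels : counts
        Voxel-count window; below = artifact, above = neuron-scale body.
    connectivity : {1, 2, 3}
        3-D neighborhood (1 = 6-, 2 = 18-, 3 = 26-connected). Default 26.
    tissue_threshold : intensity units
        Absolute cut on the raw stack separating tissue autofluorescence
        from the outside-tissue floor.
    """

    background_sigma: float = 10.0
    cell_threshold: float = 50.0
    min_voxels: int = 50
    max_voxels: int = 10000
    connectivity: int = 3
    tissue_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.min_voxels < self.max_voxels):
            raise ValueError("need 0 < min_voxels < max_voxels")
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be positive")
        if self.cell_threshold < 0 or self.tissue_threshold < 0:
            raise ValueError("thresholds must be ≥ 0")
        if self.connectivity not in (1, 2, 3):
            raise ValueError("connectivity must be 1, 2 or 3")


@dataclass
class LabeledVolume:
    """Integer label grid (0 = background) with per-object voxel counts.

    Labels are contiguous 1..K.  ``counts[i]`` is the voxel count of
    label ``i + 1``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    counts: np.ndarray

    @property
    def n_objects(self) -> int:
        return len(self.counts)

    def object_indices(self, object_id: int) -> np.ndarray:
        """Voxel indices (N×3) of one object."""
        return np.argwhere(self.labels == object_id)

    @classmethod
    def from_labels(cls, labels: np.ndarray, voxel_size) -> "LabeledVolume":
        """Relabel contiguously and tabulate counts."""
        labels = np.asarray(labels)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        out = np.zeros_like(labels, dtype=np.int32)
        counts = np.zeros(len(ids), dtype=np.int64)
        for new, old in enumerate(ids, start=1):
            mask = labels == old
            out[mask] = new
            counts[new - 1] = int(mask.sum())
        return cls(labels=out, voxel_size=tuple(voxel_size), counts=counts)


def subtract_background(stack: ImageStack, background_sigma: float = 10.0) -> ImageStack:
    """Subtract a large-scale Gaussian background estimate, clipping at 0.

    ``background_sigma`` is physical (µm) and converted per-axis to voxel
    units, so anisotropic stacks are smoothed isotropically in physical
    space.  A sigma below one voxel on any axis is allowed but warned
    about — the "background" would then track individual cells.
    """
    if background_sigma <= 0:
        raise ValueError("background_sigma must be positive")
    sigma_vox = tuple(background_sigma / v for v in stack.voxel_size)
    if min(sigma_vox) < 1.0:
        warnings.warn(
            f"background_sigma {background_sigma} µm is below one voxel on some axis "
            f"(sigma in voxels: {tuple(round(s, 2) for s in sigma_vox)}); "
            "background estimate will follow fine structure",
            stacklevel=2,
        )
    background = ndi.gaussian_filter(stack.data.astype(float), sigma=sigma_vox)
    residual = np.clip(stack.data.astype(float) - background, 0.0, None)
    return stack.with_data(residual)


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(3, connectivity)


def segment_cells(stack: ImageStack, params: SegmentationParams) -> LabeledVolume:
    """Threshold a background-subtracted stack and label connected components.

    Voxels with intensity ≥ ``cell_threshold`` are foreground.  An empty
    foreground is a valid zero-object result, not an error.
    """
    fg = stack.data >= params.cell_threshold
    labels, n = ndi.label(fg, structure=_structure(params.connectivity))
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return LabeledVolume(labels=labels.astype(np.int32), voxel_size=stack.voxel_size, counts=counts)


def filter_by_voxels(
    lv: LabeledVolume,
    min_voxels: int,
    max_voxels: float,
) -> tuple[LabeledVolume, int, int]:
    """Remove objects outside the [min_voxels, max_voxels] window.

    Returns the relabeled survivor volume plus the counts of removed
    small (artifact) and large (neuron-scale) objects.  Survivors are
    relabeled contiguously preserving their original order.
    """
    if not min_voxels < max_voxels:
        raise ValueError("min_voxels must be < max_voxels")
    keep = (lv.counts >= min_voxels) & (lv.counts <= max_voxels)
    removed_small = int((lv.counts < min_voxels).sum())
    removed_large = int((lv.counts > max_voxels).sum())
    mapping = np.zeros(lv.n_objects + 1, dtype=np.int32)
    mapping[1:][keep] = np.arange(1, keep.sum() + 1)
    out = LabeledVolume(
        labels=mapping[lv.labels],
        voxel_size=lv.voxel_size,
        counts=lv.counts[keep].copy(),
    )
    return out, removed_small, removed_large


def tissue_volume(stack: ImageStack, tissue_threshold: float, connectivity: int = 3) -> float:
    """Tissue volume in µm³ by absolute intensity thresholding of the raw stack.

    Voxels ≥ threshold are tissue candidates; only the largest connected
    component is kept (debris and lone noise voxels are ignored), and its
    voxel count is converted to physical volume.
    """
    mask = stack.data >= tissue_threshold
    if not mask.any():
        raise NoTissueError(
            f"no voxel ≥ tissue_threshold {tissue_threshold}; stack max is {stack.data.max():.3g}"
        )
    labels, n = ndi.label(mask, structure=_structure(connectivity))
    counts = np.bincount(labels.ravel())[1:]
    largest = int(counts.max())
    return largest * stack.voxel_volume
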