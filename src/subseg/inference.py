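"""Whole-volume segmentation: ROI restriction, voxel classification, cleanup.

The sub-cortical structures occupy the central brain, so classification is
restricted to a region of interest derived from the probabilistic atlas: the
voxels where some structure's atlas probability exceeds a threshold, dilated
by a few voxels.  Every ROI voxel's 2.5D patch triplet and atlas vector are
classified by the network; voxels outside the ROI stay background.  Spurious
outputs are removed by keeping, for each class, only its largest connected
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import AtlasProbability, LabelVolume, N_CLASSES, Volume
from .model import ModelState
from .preprocess import is_zscore_normalized, zscore_normalize
from .sampling import PATCH_SIZE, _extract_many

__all__ = ["InferenceError", "SegmentationResult", "make_roi", "segment",
           "keep_largest_component"]

#: 26-connectivity structuring element, consistent with the training shell.
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class InferenceError(ValueError):
    """Raised for empty ROIs or unnormalised inputs."""


@dataclass
class SegmentationResult:
    labels: LabelVolume
    roi: np.ndarray
    probabilities: np.ndarray | None = None  # (n_roi, 15) rows, ROI order
    roi_voxels: np.ndarray | None = None     # (n_roi, 3) matching rows
    n_classified: int = 0


def make_roi(atlas: AtlasProbability, threshold: float = 0.1,
             dilation: int = 3) -> np.ndarray:
    """Boolean ROI: structure-probability support thresholded then dilated."""
    structure_max = atlas.data[..., 1:].max(axis=-1)
    roi = structure_max > threshold
    if dilation > 0:
        roi = ndimage.binary_dilation(roi, structure=_STRUCT26, iterations=dilation)
    if not roi.any():
        raise InferenceError(
            f"empty ROI at threshold {threshold}; lower the threshold"
        )
    return roi


def keep_largest_component(labels: LabelVolume) -> LabelVolume:
    """For each class keep only its largest 26-connected component.

    Equal-size ties are broken deterministically in favour of the component
    containing the lexicographically smallest voxel index.
    """
    data = labels.data.copy()
    for cls in range(1, N_CLASSES):
        mask = data == cls
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=_STRUCT26)
        if n <= 1:
            continue
        sizes = np.bincount(comp.ravel())[1:]  # component ids 1..n
        best = np.max(sizes)
        ties = np.nonzero(sizes == best)[0] + 1
        if len(ties) == 1:
            keep = ties[0]
        else:
            # first tie encountered in C-order scan owns the smallest voxel
            flat = comp.ravel()
            first_pos = {c: np.argmax(flat == c) for c in ties}
            keep = min(ties, key=lambda c: first_pos[c])
        data[mask & (comp != keep)] = 0
    return LabelVolume(data=data, spacing=labels.spacing, affine=labels.affine)


def segment(model: ModelState, volume: Volume, atlas: AtlasProbability,
            roi_threshold: float = 0.1, roi_dilation: int = 3,
            normalize: bool = True, keep_probabilities: bool = False,
            chunk: int = 4096) -> SegmentationResult:
    """Segment one volume with a trained model.

    The input is z-score normalised internally (over its brain mask) unless
    already normalised; with ``normalize=False`` an unnormalised input is an
    error.  One classification per ROI voxel; argmax ties resolve to the
    lowest class index; largest-component filtering is applied last.
    """
    if volume.shape != atlas.grid_shape:
        raise InferenceError(
            f"volume shape {volume.shape} != atlas grid {atlas.grid_shape}"
        )
    if not is_zscore_normalized(volume):
        if normalize:
            volume = zscore_normalize(volume)
        else:
            raise InferenceError(
                "input volume is not z-score normalised over its brain mask"
            )
    roi = make_roi(atlas, threshold=roi_threshold, dilation=roi_dilation)
    voxels = np.argwhere(roi).astype(np.int32)
    data = np.asarray(volume.data)
    out = np.zeros(volume.shape, dtype=np.int16)
    prob_rows = [] if keep_probabilities else None
    n_classified = 0
    for lo in range(0, len(voxels), chunk):
        vox = voxels[lo:lo + chunk]
        patches = _extract_many(data, vox, PATCH_SIZE)
        atlas_vecs = atlas.data[vox[:, 0], vox[:, 1], vox[:, 2]].astype(np.float32)
        probs, _ = model.forward(patches, atlas_vecs, train=False)
        n_classified += len(vox)
        # argmax with lowest-index tie-break (numpy argmax takes the first max)
        pred = probs.argmax(axis=1)
        out[vox[:, 0], vox[:, 1], vox[:, 2]] = pred
        if prob_rows is not None:
            prob_rows.append(probs.astype(np.float32))
    labels = LabelVolume(data=out, spacing=volume.spacing, affine=volume.affine)
    labels = keep_largest_component(labels)
    return SegmentationResult(
        labels=labels,
        roi=roi,
        probabilities=np.concatenate(prob_rows) if prob_rows else None,
        roi_voxels=voxels if keep_probabilities else None,
        n_classified=n_classified,
    )
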