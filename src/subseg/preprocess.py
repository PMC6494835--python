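"""Intensity pre-processing: z-score normalisation and histogram standardisation.

Two tools are provided:

* :func:`zscore_normalize` — the per-volume zero-mean / unit-variance
  normalisation applied before training and testing.  Statistics are computed
  over the brain mask only; the affine transform is applied to the whole grid.

* Nyúl-style two-stage histogram standardisation
  (:func:`learn_standard_scale` / :func:`apply_standardisation`) — stage one
  learns a standard scale by averaging percentile landmarks over a set of
  training images; stage two maps each image's landmarks onto the standard
  scale with a monotone piecewise-linear intensity transform.  Used in the
  comparison experiments where images from both domains are brought onto a
  common intensity scale before training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import Volume

__all__ = [
    "PreprocessError",
    "DEFAULT_LANDMARK_PERCENTILES",
    "StandardScale",
    "zscore_normalize",
    "is_zscore_normalized",
    "learn_standard_scale",
    "apply_standardisation",
]


class PreprocessError(ValueError):
    """Raised for degenerate inputs (empty masks, flat histograms...)."""


#: Deciles plus robust extremes — the canonical two-stage configuration.
DEFAULT_LANDMARK_PERCENTILES: tuple[float, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


def _masked(volume: Volume) -> np.ndarray:
    if volume.mask is None:
        raise PreprocessError("volume has no brain mask")
    vals = volume.data[volume.mask]
    if vals.size == 0:
        raise PreprocessError("brain mask is empty")
    return np.asarray(vals, dtype=np.float64)


def zscore_normalize(volume: Volume) -> Volume:
    """Zero-mean, unit-variance normalisation over the brain mask."""
    vals = _masked(volume)
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise PreprocessError("constant intensity inside the brain mask (zero variance)")
    return volume.with_data(((volume.data - mu) / sd).astype(np.float32))


def is_zscore_normalized(volume: Volume, mean_tol: float = 1e-3,
                         sd_tol: float = 1e-2) -> bool:
    vals = _masked(volume)
    return abs(float(vals.mean())) <= mean_tol and abs(float(vals.std()) - 1.0) <= sd_tol


@dataclass(frozen=True)
class StandardScale:
    """A learned standard intensity scale.

    ``standard_landmarks[i]`` is the target intensity for the percentile rank
    ``landmark_percentiles[i]``; the first and last landmarks coincide with
    ``output_range``.
    """

    landmark_percentiles: tuple[float, ...]
    standard_landmarks: tuple[float, ...]
    output_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        ranks = np.asarray(self.landmark_percentiles, dtype=float)
        if ranks.ndim != 1 or len(ranks) < 2:
            raise PreprocessError("need at least two landmark percentiles")
        if np.any(ranks <= 0) or np.any(ranks >= 100) or np.any(np.diff(ranks) <= 0):
            raise PreprocessError("percentile ranks must be strictly increasing in (0, 100)")
        lm = np.asarray(self.standard_landmarks, dtype=float)
        if lm.shape != ranks.shape:
            raise PreprocessError("landmarks and ranks must have equal length")
        if np.any(np.diff(lm) < 0):
            raise PreprocessError("standard landmarks must be non-decreasing")
        if self.output_range[1] <= self.output_range[0]:
            raise PreprocessError("output_range must be increasing")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "landmark_percentiles": list(self.landmark_percentiles),
                    "standard_landmarks": list(self.standard_landmarks),
                    "output_range": list(self.output_range),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardScale":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            landmark_percentiles=tuple(raw["landmark_percentiles"]),
            standard_landmarks=tuple(raw["standard_landmarks"]),
            output_range=tuple(raw["output_range"]),
        )


def _image_landmarks(volume: Volume, ranks: Sequence[float]) -> np.ndarray:
    return np.percentile(_masked(volume), list(ranks))


def learn_standard_scale(
    volumes: Sequence[Volume],
    ranks: Sequence[float] = DEFAULT_LANDMARK_PERCENTILES,
    output_range: tuple[float, float] = (0.0, 100.0),
) -> StandardScale:
    """Stage one: learn the standard scale from training images.

    Each image's landmarks are affinely mapped so its extreme landmarks hit
    ``output_range``; the standard landmarks are the mean of these mapped
    landmark vectors.
    """
    if len(volumes) == 0:
        raise PreprocessError("learn_standard_scale needs at least one volume")
    s_min, s_max = output_range
    mapped = []
    for vol in volumes:
        lm = _image_landmarks(vol, ranks)
        if lm[-1] <= lm[0]:
            raise PreprocessError("degenerate histogram: extreme landmarks coincide")
        mapped.append(s_min + (lm - lm[0]) * (s_max - s_min) / (lm[-1] - lm[0]))
    standard = np.mean(mapped, axis=0)
    return StandardScale(
        landmark_percentiles=tuple(float(r) for r in ranks),
        standard_landmarks=tuple(float(x) for x in standard),
        output_range=(float(s_min), float(s_max)),
    )


def apply_standardisation(volume: Volume, scale: StandardScale) -> Volume:
    """Stage two: piecewise-linear map of image landmarks onto the standard scale.

    The map is monotone non-decreasing, linear between landmarks, linearly
    extended beyond the extreme landmarks and clamped to
    ``[0, 1.5 * s_max]`` to bound outliers.
    """
    lm = _image_landmarks(volume, scale.landmark_percentiles)
    if np.any(np.diff(lm) <= 0):
        raise PreprocessError(
            "image landmarks are not strictly increasing (flat histogram "
            "segment); try a coarser set of percentile ranks"
        )
    std = np.asarray(scale.standard_landmarks, dtype=np.float64)
    data = np.asarray(volume.data, dtype=np.float64)
    out = np.interp(data, lm, std)
    # linear extension beyond the extreme landmarks
    lo_slope = (std[1] - std[0]) / (lm[1] - lm[0])
    hi_slope = (std[-1] - std[-2]) / (lm[-1] - lm[-2])
    below = data < lm[0]
    above = data > lm[-1]
    out[below] = std[0] + (data[below] - lm[0]) * lo_slope
    out[above] = std[-1] + (data[above] - lm[-1]) * hi_slope
    out = np.clip(out, 0.0, 1.5 * scale.output_range[1])
    dtype = volume.data.dtype if np.issubdtype(volume.data.dtype, np.floating) else np.float32
    return volume.with_data(out.astype(dtype))
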