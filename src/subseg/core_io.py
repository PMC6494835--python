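"""Volume containers, NIfTI I/O and the sub-cortical label dictionary.

All grids in the package are addressed with 0-based voxel indices in a
canonical (RAS) axis order, so that axis 0 indexes sagittal slices, axis 1
coronal slices and axis 2 axial slices.  World coordinates are carried in the
affine but never used for patch arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelVolume",
    "AtlasProbability",
    "LABEL_NAMES",
    "N_CLASSES",
    "STRUCTURE_NAMES",
    "NiftiFormatError",
    "LabelError",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_atlas",
    "write_atlas",
    "remap_labels",
    "load_label_mapping",
]

#: Number of classes: background plus the seven bilateral structures.
N_CLASSES = 15

#: Class id -> acronym.  Odd ids are left-hemisphere, even ids right.
LABEL_NAMES: dict[int, str] = {
    0: "Bg",
    1: "Tha.L", 2: "Tha.R",
    3: "Cau.L", 4: "Cau.R",
    5: "Put.L", 6: "Put.R",
    7: "Pal.L", 8: "Pal.R",
    9: "Hip.L", 10: "Hip.R",
    11: "Amy.L", 12: "Amy.R",
    13: "Acc.L", 14: "Acc.R",
}

#: The seven structure families in decreasing typical-volume order.
STRUCTURE_NAMES = ("Tha", "Cau", "Put", "Pal", "Hip", "Amy", "Acc")


class NiftiFormatError(ValueError):
    """Raised for files that are not usable NIfTI grids (wrong ndim, NaNs...)."""


class LabelError(ValueError):
    """Raised for label volumes or mappings outside the {0..14} contract."""


@dataclass
class Volume:
    """A 3-D scalar intensity grid with spacing/affine metadata.

    ``mask`` (when present) marks the brain area; statistics such as the
    z-score normalisation are computed over the mask only.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NiftiFormatError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise NiftiFormatError("volume contains non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise NiftiFormatError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data))


@dataclass
class LabelVolume:
    """An integer grid over {0..14}; 0 is background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NiftiFormatError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise LabelError("label volume has non-integer values")
            self.data = rounded.astype(np.int16)
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < 0 or hi >= N_CLASSES:
            raise LabelError(f"label values outside 0..{N_CLASSES - 1}: min={lo} max={hi}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def present_classes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.data) if c > 0)


@dataclass
class AtlasProbability:
    """Per-voxel class probabilities, channels last, shape (X, Y, Z, 15)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise NiftiFormatError(f"atlas must be 4-D, got ndim={self.data.ndim}")
        if self.data.shape[-1] != N_CLASSES:
            raise NiftiFormatError(
                f"atlas must have {N_CLASSES} channels, got {self.data.shape[-1]}"
            )

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    def vector_at(self, voxel: tuple[int, int, int]) -> np.ndarray:
        return self.data[voxel]


def _load_canonical(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise NiftiFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    return nib.as_closest_canonical(img)


def _spacing(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return (float(z[0]), float(z[1]), float(z[2]))


def read_volume(path: str | Path, mask_path: str | Path | None = None) -> Volume:
    """Read a 3-D NIfTI, reorienting to the canonical (RAS) axis order."""
    img = _load_canonical(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NiftiFormatError(f"{path}: expected 3-D volume, got ndim={data.ndim}")
    if np.isnan(data).any():
        raise NiftiFormatError(f"{path}: volume contains NaN voxels")
    mask = None
    if mask_path is not None:
        mimg = _load_canonical(mask_path)
        mask = np.asarray(mimg.dataobj) > 0
    return Volume(data=data, spacing=_spacing(img), affine=np.asarray(img.affine), mask=mask)


def write_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data), np.asarray(volume.affine))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_labels(path: str | Path) -> LabelVolume:
    img = _load_canonical(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise NiftiFormatError(f"{path}: expected 3-D label volume, got ndim={data.ndim}")
    if np.isnan(data).any():
        raise NiftiFormatError(f"{path}: label volume contains NaN voxels")
    return LabelVolume(data=data.astype(np.int16), spacing=_spacing(img), affine=np.asarray(img.affine))


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int16), np.asarray(labels.affine))
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))


def read_atlas(path: str | Path) -> AtlasProbability:
    img = _load_canonical(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise NiftiFormatError(f"{path}: atlas must be 4-D, got ndim={data.ndim}")
    if data.shape[-1] != N_CLASSES:
        raise NiftiFormatError(
            f"{path}: atlas must have {N_CLASSES} channels, got {data.shape[-1]}"
        )
    if np.isnan(data).any():
        raise NiftiFormatError(f"{path}: atlas contains NaN voxels")
    return AtlasProbability(data=data, spacing=_spacing(img), affine=np.asarray(img.affine))


def write_atlas(atlas: AtlasProbability, path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.data.astype(np.float32), np.asarray(atlas.affine))
    nib.save(img, str(path))


def remap_labels(raw: LabelVolume | np.ndarray, mapping: Mapping[int, int],
                 spacing=None, affine=None) -> LabelVolume:
    """Map dataset-specific label ids onto the package's {0..14} dictionary.

    Ids absent from ``mapping`` become background.  Voxel counts of kept
    classes are preserved.
    """
    for src, dst in mapping.items():
        if not (0 <= int(dst) < N_CLASSES):
            raise LabelError(f"mapping target {dst} outside 0..{N_CLASSES - 1}")
    if isinstance(raw, LabelVolume):
        data = raw.data
        spacing = raw.spacing if spacing is None else spacing
        affine = raw.affine if affine is None else affine
    else:
        data = np.asarray(raw)
        spacing = (1.0, 1.0, 1.0) if spacing is None else spacing
        affine = np.eye(4) if affine is None else affine
    out = np.zeros(data.shape, dtype=np.int16)
    for src, dst in mapping.items():
        out[data == int(src)] = int(dst)
    return LabelVolume(data=out, spacing=spacing, affine=np.asarray(affine))


def load_label_mapping(path: str | Path) -> dict[int, int]:
    """Load a JSON ``{raw_id: class_id}`` remap table."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): int(v) for k, v in raw.items()}
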