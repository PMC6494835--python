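"""Seeded two-domain brain phantoms and their population atlas.

The generator emulates the aspects of real T1-weighted cohorts that drive the
segmentation and domain-adaptation pipeline, without claiming any anatomy:

* fourteen left/right-paired structures (seven families) with a wide volume
  spread, thalamus largest down to accumbens smallest;
* per-subject positional and size jitter, so a population atlas built from
  several subjects is genuinely blurred near structure boundaries;
* two acquisition "scanners" with disjoint intensity profiles — one whose
  brain intensities reach roughly 2000 and one reaching roughly 140 — plus
  additive noise, a smooth multiplicative bias field and optional
  through-plane anisotropy;
* a background-tissue intensity of its own inside the brain mask, so that
  structure/background boundary contrast exists and boundary negatives are
  meaningful training samples.

Structures are superellipsoids (exponent 2.5): smooth closed shapes whose
volume is controlled by three semi-axes.  Left/right members of a pair are
mirror images about the mid-sagittal plane before jitter is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core_io import (
    AtlasProbability,
    LabelVolume,
    N_CLASSES,
    STRUCTURE_NAMES,
    Volume,
    write_atlas,
    write_labels,
    write_volume,
)

__all__ = [
    "PhantomConfig",
    "DomainSpec",
    "PhantomError",
    "scanner_a",
    "scanner_b",
    "DOMAIN_PRESETS",
    "make_subject",
    "make_atlas",
    "make_cohort",
]


class PhantomError(ValueError):
    """Raised when a phantom cannot be generated under the given config."""


# Per-family layout: fractional (y, z) centre, fractional lateral offset from
# the mid-sagittal plane.  Chosen so that all structures stay disjoint and
# inside a 64^3 grid with the default radii and jitter.
_LAYOUT = {
    "Tha": {"offset": 0.19, "y": 0.47, "z": 0.44},
    "Cau": {"offset": 0.17, "y": 0.72, "z": 0.59},
    "Put": {"offset": 0.28, "y": 0.31, "z": 0.69},
    "Pal": {"offset": 0.19, "y": 0.25, "z": 0.31},
    "Hip": {"offset": 0.25, "y": 0.69, "z": 0.25},
    "Amy": {"offset": 0.28, "y": 0.84, "z": 0.38},
    "Acc": {"offset": 0.13, "y": 0.53, "z": 0.75},
}

# Semi-axis shape factors applied to each base radius (x, y, z); mildly
# anisotropic so structures are not spheres, close enough to 1 that the
# smallest (r=3) family keeps >= 100 voxels.
_SHAPE = (1.0, 0.9, 0.85)
_EXPONENT = 2.5

# Brain-ellipsoid semi-axes as fractions of the grid extent.
_BRAIN_FRAC = (0.44, 0.47, 0.41)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the phantom population.

    ``structure_radii`` are the seven base radii (voxels) in the fixed family
    order thalamus, caudate, putamen, pallidum, hippocampus, amygdala,
    accumbens and must be strictly decreasing, which makes structure volumes
    strictly ordered at zero jitter.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    structure_radii: tuple[float, ...] = (9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0)
    lateral_offset: tuple[float, ...] | None = None  # voxels; default from layout
    subject_jitter_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.structure_radii) != 7:
            raise PhantomError("structure_radii must have 7 entries")
        if any(r <= 0 for r in self.structure_radii):
            raise PhantomError("structure radii must be positive")
        diffs = np.diff(self.structure_radii)
        if not np.all(diffs < 0):
            raise PhantomError("structure_radii must be strictly decreasing")
        if any(s <= 0 for s in self.grid_shape) or any(s <= 0 for s in self.spacing):
            raise PhantomError("grid_shape and spacing must be positive")
        if self.subject_jitter_sd < 0:
            raise PhantomError("subject_jitter_sd must be non-negative")

    def offsets(self) -> np.ndarray:
        if self.lateral_offset is not None:
            off = np.asarray(self.lateral_offset, dtype=float)
            if off.shape != (7,):
                raise PhantomError("lateral_offset must have 7 entries")
            return off
        return np.array([_LAYOUT[s]["offset"] for s in STRUCTURE_NAMES]) * self.grid_shape[0]

    def centres(self) -> np.ndarray:
        """Unjittered structure centres, shape (14, 3); row order = class id - 1."""
        nx, ny, nz = self.grid_shape
        mid = (nx - 1) / 2.0
        offsets = self.offsets()
        out = np.zeros((14, 3))
        for fi, fam in enumerate(STRUCTURE_NAMES):
            y = _LAYOUT[fam]["y"] * ny
            z = _LAYOUT[fam]["z"] * nz
            out[2 * fi] = (mid - offsets[fi], y, z)      # left: lower x in RAS
            out[2 * fi + 1] = (mid + offsets[fi], y, z)  # right: mirror image
        return out


@dataclass(frozen=True)
class DomainSpec:
    """Intensity model of one acquisition domain.

    ``class_means`` are relative tissue intensities (one per class, including
    in-brain background tissue as class 0); the voxel model is

        intensity = bias_field * class_means[label] * intensity_scale + noise

    with additive Gaussian noise of sd ``noise_sd`` (post-scale units) inside
    the brain mask and zero intensity outside it.  Left and right members of
    a structure pair share a mean; contrast validation therefore applies to
    the distinct tissue means.
    """

    name: str
    class_means: tuple[float, ...]
    intensity_scale: float = 1.0
    noise_sd: float = 0.0
    bias_field_amplitude: float = 0.0
    anisotropy_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.class_means) != N_CLASSES:
            raise PhantomError(f"class_means must have {N_CLASSES} entries")
        if any(m < 0 for m in self.class_means):
            raise PhantomError("class_means must be non-negative")
        if self.intensity_scale <= 0 or self.noise_sd < 0:
            raise PhantomError("intensity_scale must be > 0 and noise_sd >= 0")
        if self.anisotropy_factor < 1.0:
            raise PhantomError("anisotropy_factor must be >= 1")
        means = np.unique(np.asarray(self.class_means) * self.intensity_scale)
        if len(means) > 1:
            min_gap = np.diff(np.sort(means)).min()
            if min_gap < 2.0 * self.noise_sd:
                raise PhantomError(
                    f"adjacent tissue means separated by {min_gap:.3g} < "
                    f"2*noise_sd = {2 * self.noise_sd:.3g}; contrast too low"
                )


def _means(bg: float, tha: float, cau: float, put: float, pal: float,
           hip: float, amy: float, acc: float) -> tuple[float, ...]:
    per_family = (tha, tha, cau, cau, put, put, pal, pal, hip, hip, amy, amy, acc, acc)
    return (bg,) + per_family


def scanner_a() -> DomainSpec:
    """High-intensity-range domain: brain maximum near 2000."""
    return DomainSpec(
        name="scannerA",
        class_means=_means(bg=0.30, tha=0.52, cau=0.44, put=0.58,
                           pal=0.72, hip=0.38, amy=0.65, acc=0.86),
        intensity_scale=2000.0,
        noise_sd=40.0,
        bias_field_amplitude=0.05,
        anisotropy_factor=1.0,
    )


def scanner_b() -> DomainSpec:
    """Low-intensity-range domain: brain maximum near 140, different tissue
    contrast ordering and mild through-plane anisotropy."""
    return DomainSpec(
        name="scannerB",
        class_means=_means(bg=0.50, tha=0.30, cau=0.80, put=0.90,
                           pal=0.40, hip=0.70, amy=0.25, acc=0.60),
        intensity_scale=140.0,
        noise_sd=2.8,
        bias_field_amplitude=0.08,
        anisotropy_factor=1.5,
    )


DOMAIN_PRESETS = {"scannerA": scanner_a, "scannerB": scanner_b}


def _superellipsoid_mask(shape: Sequence[int], centre: np.ndarray,
                         radii: np.ndarray, exponent: float = _EXPONENT) -> np.ndarray:
    lo = np.maximum(np.floor(centre - radii - 1).astype(int), 0)
    hi = np.minimum(np.ceil(centre + radii + 2).astype(int), np.asarray(shape))
    if np.any(lo >= hi):
        return np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    acc = np.zeros(grids[0].shape)
    for g, c, r in zip(grids, centre, radii):
        acc += np.abs((g - c) / r) ** exponent
    out = np.zeros(shape, dtype=bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = acc <= 1.0
    return out


def _paint_labels(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    shape = config.grid_shape
    centres = config.centres()
    labels = np.zeros(shape, dtype=np.int16)
    sd = config.subject_jitter_sd
    for cls in range(1, 15):
        fam = (cls - 1) // 2
        base_r = config.structure_radii[fam]
        centre = centres[cls - 1].copy()
        radii = base_r * np.asarray(_SHAPE)
        if sd > 0:
            jitter = np.clip(rng.normal(0.0, sd, size=3), -2 * sd, 2 * sd)
            centre = centre + jitter
            size_sd = sd / 25.0
            radii = radii * (1.0 + np.clip(rng.normal(0.0, size_sd), -2 * size_sd, 2 * size_sd))
        if np.any(centre - radii < 0) or np.any(centre + radii > np.asarray(shape) - 1):
            from .core_io import LABEL_NAMES
            raise PhantomError(
                f"structure {LABEL_NAMES[cls]} out of bounds after jitter "
                f"(centre {np.round(centre, 2).tolist()}, radii {np.round(radii, 2).tolist()})"
            )
        mask = _superellipsoid_mask(shape, centre, radii)
        if not mask.any():
            from .core_io import LABEL_NAMES
            raise PhantomError(f"structure {LABEL_NAMES[cls]} produced no voxels")
        labels[mask] = cls
    return labels


def _brain_mask(config: PhantomConfig, labels: np.ndarray) -> np.ndarray:
    shape = np.asarray(config.grid_shape)
    centre = (shape - 1) / 2.0
    radii = np.asarray(_BRAIN_FRAC) * shape
    ellipsoid = _superellipsoid_mask(config.grid_shape, centre, radii, exponent=2.0)
    return ellipsoid | (labels > 0)


def _bias_field(shape: Sequence[int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * f, with f in [-1, 1]."""
    if amplitude == 0:
        return np.ones(shape)
    coarse = rng.normal(size=(4, 4, 4))
    field_ = ndimage.zoom(coarse, np.asarray(shape) / 4.0, order=3)
    field_ = field_[tuple(slice(0, s) for s in shape)]
    peak = np.max(np.abs(field_))
    if peak > 0:
        field_ = field_ / peak
    return 1.0 + amplitude * field_


def _apply_anisotropy(data: np.ndarray, factor: float) -> np.ndarray:
    """Mimic thick slices: blur + subsample along axis 2, resample back."""
    if factor <= 1.0:
        return data
    sigma = 0.425 * np.sqrt(factor**2 - 1.0)
    blurred = ndimage.gaussian_filter1d(data, sigma=sigma, axis=2)
    n = data.shape[2]
    coarse_n = max(2, int(round(n / factor)))
    coarse = ndimage.zoom(blurred, (1, 1, coarse_n / n), order=1)
    back = ndimage.zoom(coarse, (1, 1, n / coarse.shape[2]), order=1)
    return back[:, :, :n]


def make_subject(config: PhantomConfig, domain: DomainSpec,
                 subject_seed: int) -> tuple[Volume, LabelVolume]:
    """Generate one phantom subject; deterministic in (config, domain, seed)."""
    rng = np.random.default_rng([config.seed, subject_seed])
    labels = _paint_labels(config, rng)
    brain = _brain_mask(config, labels)

    means = np.asarray(domain.class_means, dtype=np.float64)
    intensity = means[labels] * domain.intensity_scale
    bias = _bias_field(config.grid_shape, domain.bias_field_amplitude, rng)
    intensity = bias * intensity
    if domain.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, domain.noise_sd, size=intensity.shape)
    intensity[~brain] = 0.0
    intensity = _apply_anisotropy(intensity, domain.anisotropy_factor)
    intensity[~brain] = 0.0

    spacing = config.spacing
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    vol = Volume(data=intensity.astype(np.float32), spacing=spacing, affine=affine, mask=brain)
    lab = LabelVolume(data=labels, spacing=spacing, affine=affine)
    missing = set(range(1, 15)) - set(lab.present_classes())
    if missing:
        raise PhantomError(f"generated phantom missing classes {sorted(missing)}")
    return vol, lab


def make_atlas(labels: Sequence[LabelVolume], smoothing_sd: float = 2.0) -> AtlasProbability:
    """Population atlas: smoothed mean one-hot encoding, renormalised per voxel.

    ``smoothing_sd`` is in millimetres; 0 disables smoothing, making the
    single-subject atlas the exact one-hot encoding of its label map.
    """
    if len(labels) == 0:
        raise PhantomError("make_atlas needs at least one label volume")
    shape = labels[0].shape
    for lab in labels:
        if lab.shape != shape:
            raise PhantomError(f"label shape mismatch: {lab.shape} != {shape}")
    spacing = labels[0].spacing
    mean = np.zeros(shape + (N_CLASSES,), dtype=np.float64)
    for lab in labels:
        for c in range(N_CLASSES):
            mean[..., c] += (lab.data == c)
    mean /= len(labels)
    if smoothing_sd > 0:
        sigma_vox = [smoothing_sd / s for s in spacing]
        for c in range(N_CLASSES):
            mean[..., c] = ndimage.gaussian_filter(mean[..., c], sigma=sigma_vox)
    total = mean.sum(axis=-1, keepdims=True)
    total[total == 0] = 1.0
    mean /= total
    return AtlasProbability(data=mean.astype(np.float32), spacing=spacing,
                            affine=labels[0].affine)


def make_cohort(out_dir: str | Path, config: PhantomConfig, domain: DomainSpec,
                n_subjects: int, atlas_smoothing_sd: float = 2.0,
                atlas_subjects: Sequence[int] | None = None) -> dict:
    """Write a phantom cohort to disk as NIfTI files plus a manifest.

    Produces ``sub-XXX_T1.nii.gz``, ``sub-XXX_labels.nii.gz``,
    ``sub-XXX_mask.nii.gz`` per subject, ``atlas.nii.gz`` (4-D, 15 channels in
    class-id order, built from ``atlas_subjects`` — default: all subjects) and
    ``cohort.json`` recording seeds and the domain name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "domain": domain.name,
        "config_seed": config.seed,
        "n_subjects": n_subjects,
        "subjects": [],
        "atlas_smoothing_sd": atlas_smoothing_sd,
    }
    label_volumes = []
    for i in range(n_subjects):
        vol, lab = make_subject(config, domain, subject_seed=i)
        sid = f"sub-{i:03d}"
        write_volume(vol, out / f"{sid}_T1.nii.gz")
        write_labels(lab, out / f"{sid}_labels.nii.gz")
        mask_vol = Volume(data=vol.mask.astype(np.uint8), spacing=vol.spacing, affine=vol.affine)
        write_volume(mask_vol, out / f"{sid}_mask.nii.gz")
        manifest["subjects"].append({"id": sid, "seed": i})
        label_volumes.append(lab)
    if atlas_subjects is None:
        atlas_labels = label_volumes
        manifest["atlas_subjects"] = [s["id"] for s in manifest["subjects"]]
    else:
        atlas_labels = [label_volumes[i] for i in atlas_subjects]
        manifest["atlas_subjects"] = [f"sub-{i:03d}" for i in atlas_subjects]
    atlas = make_atlas(atlas_labels, smoothing_sd=atlas_smoothing_sd)
    write_atlas(atlas, out / "atlas.nii.gz")
    with open(out / "cohort.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
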