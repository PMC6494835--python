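"""Training-set construction: 2.5D patches, atlas vectors, boundary negatives.

Every training/testing unit is a :class:`Sample`: three orthogonal 32x32
intensity tiles centred on one voxel (axial, sagittal, coronal order), the
15-element atlas probability vector at that voxel, and the class label.
Positive samples come from all structure voxels; background (negative)
samples come only from the boundary shell obtained by dilating the structure
foreground by five voxels, so the classifier concentrates on the hard
decisions at structure borders.

Conventions (the patch arithmetic relies on them):

* tiles span the half-open window ``[c - 16, c + 16)`` on each in-plane axis,
  so the source voxel sits at tile index ``(16, 16)``;
* positions outside the grid are zero-filled;
* the dilation structuring element is the 26-connected cube applied
  iteratively, i.e. "five voxels" is a Chebyshev distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import ndimage

from .core_io import AtlasProbability, LabelVolume, N_CLASSES, Volume

__all__ = [
    "PATCH_SIZE",
    "SamplingError",
    "Sample",
    "SampleSet",
    "boundary_shell",
    "extract_patch_triplet",
    "build_sample_set",
    "split_samples",
]

PATCH_SIZE = 32


class SamplingError(ValueError):
    """Raised for invalid sampling inputs (empty foreground, shape mismatch...)."""


@dataclass(frozen=True)
class Sample:
    """One voxel's 2.5D patch triplet, atlas vector and label."""

    patches: np.ndarray  # (3, 32, 32) axial, sagittal, coronal
    atlas_vector: np.ndarray  # (15,)
    label: int
    voxel: tuple[int, int, int]
    subject: str = ""


@dataclass
class SampleSet:
    """A columnar batch of samples plus provenance.

    ``patches`` has shape (n, 3, 32, 32); ``atlas_vectors`` (n, 15);
    ``labels`` (n,); ``voxels`` (n, 3); ``subject_ids`` (n,) indexes into
    ``subjects``.
    """

    patches: np.ndarray
    atlas_vectors: np.ndarray
    labels: np.ndarray
    voxels: np.ndarray
    subjects: list[str] = field(default_factory=list)
    subject_ids: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.subject_ids is None:
            self.subject_ids = np.zeros(n, dtype=np.int32)
        for name, arr, lead in (
            ("patches", self.patches, (n, 3, PATCH_SIZE, PATCH_SIZE)),
            ("atlas_vectors", self.atlas_vectors, (n, N_CLASSES)),
            ("voxels", self.voxels, (n, 3)),
            ("subject_ids", self.subject_ids, (n,)),
        ):
            if tuple(arr.shape) != lead:
                raise SamplingError(f"{name} shape {arr.shape} != {lead}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels.astype(int), minlength=N_CLASSES)

    def sample(self, i: int) -> Sample:
        sid = int(self.subject_ids[i])
        return Sample(
            patches=self.patches[i],
            atlas_vector=self.atlas_vectors[i],
            label=int(self.labels[i]),
            voxel=tuple(int(v) for v in self.voxels[i]),
            subject=self.subjects[sid] if self.subjects else "",
        )

    def select(self, idx: np.ndarray) -> "SampleSet":
        return SampleSet(
            patches=self.patches[idx],
            atlas_vectors=self.atlas_vectors[idx],
            labels=self.labels[idx],
            voxels=self.voxels[idx],
            subjects=list(self.subjects),
            subject_ids=self.subject_ids[idx],
            seed=self.seed,
        )

    def subsample(self, n: int, seed: int = 0) -> "SampleSet":
        """Deterministic stratified subsample of at most ``n`` samples.

        Per-class quotas are proportional to class frequency but every
        present class keeps at least one sample.
        """
        total = len(self)
        if n >= total:
            return self
        rng = np.random.default_rng(seed)
        counts = self.class_counts
        present = np.nonzero(counts)[0]
        quotas = {int(c): max(1, int(round(n * counts[c] / total))) for c in present}
        # trim overshoot from the most numerous classes
        while sum(quotas.values()) > n:
            c = max(quotas, key=lambda k: quotas[k])
            quotas[c] -= 1
        keep = []
        for c, q in quotas.items():
            idx = np.nonzero(self.labels == c)[0]
            keep.append(rng.choice(idx, size=min(q, len(idx)), replace=False))
        idx = np.sort(np.concatenate(keep))
        return self.select(idx)

    @staticmethod
    def concatenate(sets: Sequence["SampleSet"]) -> "SampleSet":
        """Multiset union; provenance (subject names) is preserved."""
        if len(sets) == 0:
            raise SamplingError("concatenate needs at least one sample set")
        subjects: list[str] = []
        sid_chunks = []
        for s in sets:
            local = s.subjects if s.subjects else [""]
            offset = len(subjects)
            subjects.extend(local)
            sid_chunks.append(s.subject_ids + offset)
        return SampleSet(
            patches=np.concatenate([s.patches for s in sets]),
            atlas_vectors=np.concatenate([s.atlas_vectors for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            voxels=np.concatenate([s.voxels for s in sets]),
            subjects=subjects,
            subject_ids=np.concatenate(sid_chunks),
            seed=sets[0].seed,
        )

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("patches", data=self.patches, compression="gzip")
            fh.create_dataset("atlas_vectors", data=self.atlas_vectors, compression="gzip")
            fh.create_dataset("labels", data=self.labels)
            fh.create_dataset("voxels", data=self.voxels)
            fh.create_dataset("subject_ids", data=self.subject_ids)
            fh.attrs["subjects"] = ";".join(self.subjects)
            if self.seed is not None:
                fh.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path: str | Path) -> "SampleSet":
        with h5py.File(path, "r") as fh:
            subjects = fh.attrs.get("subjects", "")
            return cls(
                patches=fh["patches"][:],
                atlas_vectors=fh["atlas_vectors"][:],
                labels=fh["labels"][:],
                voxels=fh["voxels"][:],
                subjects=subjects.split(";") if subjects else [],
                subject_ids=fh["subject_ids"][:],
                seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            )


def boundary_shell(labels: LabelVolume | np.ndarray, radius: int = 5) -> np.ndarray:
    """Background shell within Chebyshev distance ``radius`` of the foreground.

    Dilates the union of all structures with a 26-connected cube, iterated
    ``radius`` times, and removes the foreground itself.
    """
    if radius < 1:
        raise SamplingError("radius must be >= 1")
    data = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    fg = data > 0
    if not fg.any():
        raise SamplingError("boundary_shell: empty foreground")
    struct = np.ones((3, 3, 3), dtype=bool)
    dilated = ndimage.binary_dilation(fg, structure=struct, iterations=radius)
    return dilated & ~fg


def extract_patch_triplet(volume: Volume | np.ndarray, voxel: tuple[int, int, int],
                          size: int = PATCH_SIZE) -> np.ndarray:
    """The three orthogonal tiles for one voxel, shape (3, size, size).

    Order: axial (in-plane axes 0,1 through slice ``k``), sagittal (axes 1,2
    through ``i``), coronal (axes 0,2 through ``j``).  Out-of-grid positions
    are zero-filled; ``tile[size//2, size//2]`` equals the voxel value.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    i, j, k = (int(v) for v in voxel)
    if not (0 <= i < data.shape[0] and 0 <= j < data.shape[1] and 0 <= k < data.shape[2]):
        raise SamplingError(f"voxel {voxel} outside grid {data.shape}")
    half = size // 2
    out = np.zeros((3, size, size), dtype=np.float32)
    planes = (
        (data[:, :, k], (i, j)),  # axial
        (data[i, :, :], (j, k)),  # sagittal
        (data[:, j, :], (i, k)),  # coronal
    )
    for t, (plane, (ci, cj)) in enumerate(planes):
        lo0, hi0 = ci - half, ci + half
        lo1, hi1 = cj - half, cj + half
        src0 = slice(max(lo0, 0), min(hi0, plane.shape[0]))
        src1 = slice(max(lo1, 0), min(hi1, plane.shape[1]))
        dst0 = slice(src0.start - lo0, src0.stop - lo0)
        dst1 = slice(src1.start - lo1, src1.stop - lo1)
        out[t, dst0, dst1] = plane[src0, src1]
    return out


def _extract_many(data: np.ndarray, voxels: np.ndarray, size: int) -> np.ndarray:
    """Vectorised patch triplets for many voxels via a zero-padded copy."""
    half = size // 2
    padded = np.pad(data, half, mode="constant").astype(np.float32)
    n = len(voxels)
    out = np.empty((n, 3, size, size), dtype=np.float32)
    iv = voxels[:, 0] + half
    jv = voxels[:, 1] + half
    kv = voxels[:, 2] + half
    offs = np.arange(-half, half)
    # axial: [i+di, j+dj, k]
    out[:, 0] = padded[
        (iv[:, None, None] + offs[None, :, None]),
        (jv[:, None, None] + offs[None, None, :]),
        kv[:, None, None],
    ]
    # sagittal: [i, j+dj, k+dk]
    out[:, 1] = padded[
        iv[:, None, None],
        (jv[:, None, None] + offs[None, :, None]),
        (kv[:, None, None] + offs[None, None, :]),
    ]
    # coronal: [i+di, j, k+dk]
    out[:, 2] = padded[
        (iv[:, None, None] + offs[None, :, None]),
        jv[:, None, None],
        (kv[:, None, None] + offs[None, None, :]),
    ]
    return out


def build_sample_set(volume: Volume, labels: LabelVolume, atlas: AtlasProbability,
                     negatives: str = "all", seed: int = 0,
                     shell_radius: int = 5, subject: str = "",
                     max_samples: int | None = None,
                     min_per_class: int = 0) -> SampleSet:
    """Assemble the training samples for one subject.

    Positives are all structure voxels; negatives are drawn from the
    ``shell_radius``-voxel boundary shell.  ``negatives`` policy:

    * ``"all"`` — every shell voxel (default);
    * ``"balanced"`` — a seeded random subset of shell voxels matching the
      positive count (all shell voxels if the shell is smaller).

    ``max_samples`` (optional) caps the total count with a seeded,
    class-stratified subsample chosen before patch extraction, so large
    cohorts can be sampled cheaply.  ``min_per_class`` keeps at least that
    many voxels of every present class (all of them for smaller classes), so
    the smallest structures are not starved by a proportional cap.
    """
    if atlas is None:
        raise SamplingError("atlas is mandatory: the network consumes spatial priors")
    if volume.shape != labels.shape or atlas.grid_shape != volume.shape:
        raise SamplingError(
            f"shape mismatch: volume {volume.shape}, labels {labels.shape}, "
            f"atlas {atlas.grid_shape}"
        )
    rng = np.random.default_rng(seed)
    pos = np.argwhere(labels.data > 0)
    shell = boundary_shell(labels, radius=shell_radius)
    neg = np.argwhere(shell)
    if negatives == "balanced" and len(neg) > len(pos):
        neg = neg[np.sort(rng.choice(len(neg), size=len(pos), replace=False))]
    elif negatives not in ("all", "balanced"):
        raise SamplingError(f"unknown negatives policy {negatives!r}")
    voxels = np.concatenate([pos, neg]).astype(np.int32)
    if max_samples is not None and len(voxels) > max_samples:
        lab_all = labels.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        counts = np.bincount(lab_all, minlength=N_CLASSES)
        present = np.nonzero(counts)[0]
        total = len(voxels)
        floors = {int(c): min(max(1, min_per_class), int(counts[c])) for c in present}
        quotas = {int(c): max(floors[int(c)], int(round(max_samples * counts[c] / total)))
                  for c in present}
        while sum(quotas.values()) > max_samples:
            above = [c for c in quotas if quotas[c] > floors[c]]
            c = max(above or quotas, key=lambda k: quotas[k])
            quotas[c] -= 1
        keep = [rng.choice(np.nonzero(lab_all == c)[0], size=min(q, counts[c]),
                           replace=False)
                for c, q in quotas.items()]
        voxels = voxels[np.sort(np.concatenate(keep))]
    patches = _extract_many(np.asarray(volume.data), voxels, PATCH_SIZE)
    atlas_vecs = atlas.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]].astype(np.float32)
    lab = labels.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]].astype(np.int16)
    return SampleSet(
        patches=patches,
        atlas_vectors=atlas_vecs,
        labels=lab,
        voxels=voxels,
        subjects=[subject] if subject else [],
        subject_ids=np.zeros(len(lab), dtype=np.int32),
        seed=seed,
    )


def split_samples(samples: SampleSet, fraction: float = 0.75,
                  seed: int = 0) -> tuple[SampleSet, SampleSet]:
    """Random disjoint, exhaustive train/validation split (default 75/25)."""
    n = len(samples)
    if n < 4:
        raise SamplingError(f"need at least 4 samples to split, got {n}")
    if not (0.0 < fraction < 1.0):
        raise SamplingError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return samples.select(np.sort(perm[:n_train])), samples.select(np.sort(perm[n_train:]))
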