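"""The three-path 2.5D patch classifier with atlas-probability fusion.

Architecture: each of the three orthogonal 32x32 patches is processed by its
own path of five convolutional layers (rectifier after each) followed by a
path-wise fully connected layer.  The three path outputs are concatenated
together with the 15 atlas probabilities — with the default path width of 180
units this concatenation is the 555-dimensional feature vector — and two
further fully connected layers (fusion + softmax classifier) produce the
15-way class posterior.

Parameters are partitioned into named groups

    conv_axial, conv_sagittal, conv_coronal,
    fc_axial, fc_sagittal, fc_coronal, fusion_fc, classifier

each with an independent trainable flag.  The transfer-learning protocol
freezes the conv groups, fine-tunes the FC groups and re-initialises the
classifier; freezing is enforced by the trainer (frozen groups receive no
optimizer updates and remain bit-identical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_io import N_CLASSES
from .nn import Adam, Conv2D, Dense, ReLU, cross_entropy_grad, he_uniform, softmax
from .sampling import PATCH_SIZE

__all__ = [
    "ModelError",
    "NetworkSpec",
    "ModelState",
    "PATH_NAMES",
    "CONV_GROUPS",
    "FC_GROUPS",
    "GROUP_NAMES",
    "build_network",
    "predict_batch",
    "extract_features",
    "trainable_parameter_count",
    "total_parameter_count",
]

PATH_NAMES = ("axial", "sagittal", "coronal")
CONV_GROUPS = tuple(f"conv_{p}" for p in PATH_NAMES)
FC_GROUPS = tuple(f"fc_{p}" for p in PATH_NAMES) + ("fusion_fc",)
GROUP_NAMES = CONV_GROUPS + FC_GROUPS + ("classifier",)


class ModelError(ValueError):
    """Raised for invalid network specifications or malformed batches."""


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the classifier.

    ``conv_channels`` must list exactly five output widths (one per conv
    layer of each path).  ``conv_strides`` is a package extension for
    desk-scale CPU runs; all-ones reproduces the stride-free default.
    """

    conv_channels: tuple[int, ...] = (32, 32, 64, 64, 128)
    kernel_size: int = 3
    conv_strides: tuple[int, ...] = (1, 1, 1, 1, 1)
    path_fc_units: int = 180
    fusion_fc_units: int = 270
    n_classes: int = N_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 5:
            raise ModelError("conv_channels must list exactly 5 widths")
        if len(self.conv_strides) != 5:
            raise ModelError("conv_strides must list exactly 5 strides")
        if self.n_classes != N_CLASSES:
            raise ModelError(f"n_classes must be {N_CLASSES}")
        if self.path_fc_units < 1 or self.fusion_fc_units < 1:
            raise ModelError("fully connected widths must be positive")

    @property
    def concat_width(self) -> int:
        return 3 * self.path_fc_units + N_CLASSES

    def conv_output_hw(self) -> int:
        n = PATCH_SIZE
        p = self.kernel_size // 2
        for s in self.conv_strides:
            n = (n + 2 * p - self.kernel_size) // s + 1
        return n

    @classmethod
    def compact(cls, seed: int = 0) -> "NetworkSpec":
        """Reduced preset for CPU-scale phantom experiments."""
        return cls(
            conv_channels=(8, 8, 16, 16, 16),
            conv_strides=(2, 2, 2, 1, 1),
            path_fc_units=32,
            fusion_fc_units=64,
            seed=seed,
        )


@dataclass
class ModelState:
    """Network parameters partitioned into named, freezable groups."""

    spec: NetworkSpec
    conv_layers: dict  # path -> list[Conv2D]
    relu_conv: dict    # path -> list[ReLU]
    path_fc: dict      # path -> Dense
    relu_fc: dict      # path -> ReLU
    fusion_fc: "Dense"
    relu_fusion: "ReLU"
    classifier: "Dense"
    trainable: dict[str, bool] = field(default_factory=lambda: {g: True for g in GROUP_NAMES})
    history: dict = field(default_factory=lambda: {"loss": [], "val_accuracy": []})

    # ---- parameter bookkeeping -------------------------------------------

    def group_layers(self, group: str):
        if group.startswith("conv_"):
            return self.conv_layers[group.split("_", 1)[1]]
        if group.startswith("fc_"):
            return [self.path_fc[group.split("_", 1)[1]]]
        if group == "fusion_fc":
            return [self.fusion_fc]
        if group == "classifier":
            return [self.classifier]
        raise ModelError(f"unknown parameter group {group!r}")

    def group_params(self, group: str) -> list[np.ndarray]:
        return [p for layer in self.group_layers(group) for p in layer.params]

    def group_pairs(self, group: str):
        return [
            (p, g)
            for layer in self.group_layers(group)
            for p, g in zip(layer.params, layer.grads)
        ]

    def set_trainable(self, group: str, flag: bool) -> None:
        if group not in self.trainable:
            raise ModelError(f"unknown parameter group {group!r}")
        self.trainable[group] = flag

    def snapshot(self) -> dict[str, list[np.ndarray]]:
        return {g: [p.copy() for p in self.group_params(g)] for g in GROUP_NAMES}

    def restore(self, snap: dict[str, list[np.ndarray]]) -> None:
        for g in GROUP_NAMES:
            for p, saved in zip(self.group_params(g), snap[g]):
                p[...] = saved

    def reinit_classifier(self, seed: int) -> None:
        rng = np.random.default_rng([int(seed), 97])
        fan_in = self.classifier.W.shape[1]
        self.classifier.W[...] = he_uniform(rng, self.classifier.W.shape, fan_in)
        self.classifier.b[...] = 0.0

    # ---- forward / backward ----------------------------------------------

    def _check_batch(self, patches: np.ndarray, atlas: np.ndarray) -> None:
        if patches.ndim != 4 or patches.shape[1:] != (3, PATCH_SIZE, PATCH_SIZE):
            raise ModelError(f"patches must be (n, 3, {PATCH_SIZE}, {PATCH_SIZE}), got {patches.shape}")
        if atlas.ndim != 2 or atlas.shape != (patches.shape[0], N_CLASSES):
            raise ModelError(f"atlas vectors must be (n, {N_CLASSES}), got {atlas.shape}")

    def forward(self, patches: np.ndarray, atlas: np.ndarray,
                train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Returns (probabilities, concatenation features)."""
        self._check_batch(patches, atlas)
        feats = []
        for t, path in enumerate(PATH_NAMES):
            h = np.ascontiguousarray(patches[:, t:t + 1].astype(np.float32))
            for conv, relu in zip(self.conv_layers[path], self.relu_conv[path]):
                h = relu.forward(conv.forward(h, train), train)
            h = h.reshape(h.shape[0], -1)
            h = self.relu_fc[path].forward(self.path_fc[path].forward(h, train), train)
            feats.append(h)
        concat = np.concatenate(feats + [atlas.astype(np.float32)], axis=1)
        g = self.relu_fusion.forward(self.fusion_fc.forward(concat, train), train)
        logits = self.classifier.forward(g, train)
        return softmax(logits), concat

    def backward(self, dlogits: np.ndarray) -> None:
        dg = self.classifier.backward(dlogits)
        dconcat = self.fusion_fc.backward(self.relu_fusion.backward(dg))
        w = self.spec.path_fc_units
        for t, path in enumerate(PATH_NAMES):
            dpath = dconcat[:, t * w:(t + 1) * w]
            dh = self.path_fc[path].backward(self.relu_fc[path].backward(dpath))
            hw = self.spec.conv_output_hw()
            dh = dh.reshape(dh.shape[0], self.spec.conv_channels[-1], hw, hw)
            for conv, relu in zip(reversed(self.conv_layers[path]), reversed(self.relu_conv[path])):
                dh = conv.backward(relu.backward(dh))
        # gradient w.r.t. the atlas slot of the concatenation is discarded

    def train_step(self, patches: np.ndarray, atlas: np.ndarray,
                   labels: np.ndarray, optimizer: Adam) -> float:
        probs, _ = self.forward(patches, atlas, train=True)
        loss, dlogits = cross_entropy_grad(probs, labels.astype(int))
        self.backward(dlogits)
        optimizer.step()
        return loss


def build_network(spec: NetworkSpec) -> ModelState:
    """Construct the network with seeded, deterministic initialisation."""
    conv_layers: dict = {}
    relu_conv: dict = {}
    path_fc: dict = {}
    relu_fc: dict = {}
    for t, path in enumerate(PATH_NAMES):
        rng = np.random.default_rng([int(spec.seed), t])
        layers = []
        cin = 1
        for li, (cout, stride) in enumerate(zip(spec.conv_channels, spec.conv_strides)):
            layers.append(Conv2D(cin, cout, spec.kernel_size, stride=stride, rng=rng))
            cin = cout
        conv_layers[path] = layers
        relu_conv[path] = [ReLU() for _ in layers]
        hw = spec.conv_output_hw()
        if hw < 1:
            raise ModelError("conv strides collapse the patch below 1x1")
        path_fc[path] = Dense(spec.conv_channels[-1] * hw * hw, spec.path_fc_units, rng=rng)
        relu_fc[path] = ReLU()
    rng = np.random.default_rng([int(spec.seed), 10])
    fusion = Dense(spec.concat_width, spec.fusion_fc_units, rng=rng)
    classifier = Dense(spec.fusion_fc_units, spec.n_classes, rng=rng)
    return ModelState(
        spec=spec,
        conv_layers=conv_layers,
        relu_conv=relu_conv,
        path_fc=path_fc,
        relu_fc=relu_fc,
        fusion_fc=fusion,
        relu_fusion=ReLU(),
        classifier=classifier,
    )


def predict_batch(model: ModelState, patches: np.ndarray, atlas: np.ndarray,
                  chunk: int = 1024) -> np.ndarray:
    """Row-stochastic class probabilities, deterministic in evaluation mode."""
    model._check_batch(np.asarray(patches), np.asarray(atlas))
    out = []
    for lo in range(0, len(patches), chunk):
        probs, _ = model.forward(patches[lo:lo + chunk], atlas[lo:lo + chunk], train=False)
        out.append(probs)
    return np.concatenate(out)


def extract_features(model: ModelState, patches: np.ndarray, atlas: np.ndarray,
                     chunk: int = 1024) -> np.ndarray:
    """Concatenation-layer vectors; the last 15 entries are the atlas vector."""
    model._check_batch(np.asarray(patches), np.asarray(atlas))
    out = []
    for lo in range(0, len(patches), chunk):
        _, feats = model.forward(patches[lo:lo + chunk], atlas[lo:lo + chunk], train=False)
        out.append(feats)
    return np.concatenate(out)


def total_parameter_count(model: ModelState) -> int:
    return sum(p.size for g in GROUP_NAMES for p in model.group_params(g))


def trainable_parameter_count(model: ModelState) -> int:
    return sum(
        p.size for g in GROUP_NAMES if model.trainable[g] for p in model.group_params(g)
    )


# ---- checkpointing ---------------------------------------------------------

def save_checkpoint(model: ModelState, path: str | Path) -> None:
    """Single-file checkpoint: parameters, group flags, spec and history."""
    arrays = {}
    for g in GROUP_NAMES:
        for i, p in enumerate(model.group_params(g)):
            arrays[f"{g}/{i}"] = p
    meta = {
        "spec": asdict(model.spec),
        "trainable": model.trainable,
        "history": model.history,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_d = meta["spec"]
        for key in ("conv_channels", "conv_strides"):
            spec_d[key] = tuple(spec_d[key])
        model = build_network(NetworkSpec(**spec_d))
        for g in GROUP_NAMES:
            for i, p in enumerate(model.group_params(g)):
                p[...] = data[f"{g}/{i}"]
    model.trainable = {k: bool(v) for k, v in meta["trainable"].items()}
    model.history = meta["history"]
    return model
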