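"""Full network training and the transfer-learning (freeze/fine-tune/reset) protocol.

Training minimises the categorical cross-entropy on shuffled mini-batches of
128 samples with Adam (initial learning rate 1e-2) for up to 200 epochs,
with early stopping: if the validation accuracy does not improve for
``patience`` (20) consecutive epochs, training stops and the parameters of
the best-validation epoch are restored.

Transfer learning adapts a trained source model to a new domain: all
convolutional groups are frozen (bit-exactly — they receive no optimizer
updates), the softmax classifier is re-initialised from scratch, and the
fully connected groups are fine-tuned from their source values at a reduced
learning rate of 1e-4.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .model import (
    CONV_GROUPS,
    FC_GROUPS,
    GROUP_NAMES,
    ModelError,
    ModelState,
)
from .nn import Adam
from .sampling import SampleSet

__all__ = ["TrainError", "TrainConfig", "TransferConfig", "train", "transfer",
           "assemble_mixed_set", "validation_accuracy"]


class TrainError(ValueError):
    """Raised for empty sample sets, bad configs or non-finite losses."""


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 20
    learning_rate: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise TrainError("learning_rate must be > 0")
        if self.max_epochs > 0 and not self.patience < self.max_epochs:
            raise TrainError("patience must be < max_epochs")


@dataclass(frozen=True)
class TransferConfig:
    """Configuration of the freeze/fine-tune/reset protocol.

    The three group sets must partition the model's parameter groups.
    Batch size, epoch budget and patience are inherited from ``base``.
    """

    learning_rate: float = 1e-4
    freeze_groups: tuple[str, ...] = CONV_GROUPS
    finetune_groups: tuple[str, ...] = FC_GROUPS
    reset_groups: tuple[str, ...] = ("classifier",)
    base: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        all_groups = self.freeze_groups + self.finetune_groups + self.reset_groups
        if sorted(all_groups) != sorted(GROUP_NAMES):
            raise ModelError(
                "freeze/finetune/reset groups must partition the model groups; "
                f"got {sorted(all_groups)}"
            )


def validation_accuracy(model: ModelState, val: SampleSet, chunk: int = 1024) -> float:
    """Fraction of validation samples whose argmax class matches the label."""
    correct = 0
    for lo in range(0, len(val), chunk):
        probs, _ = model.forward(val.patches[lo:lo + chunk],
                                 val.atlas_vectors[lo:lo + chunk], train=False)
        correct += int((probs.argmax(axis=1) == val.labels[lo:lo + chunk]).sum())
    return correct / len(val)


def train(
    model: ModelState,
    train_set: SampleSet,
    val_set: SampleSet,
    cfg: TrainConfig,
    metric: Callable[[ModelState, SampleSet], float] | None = None,
) -> ModelState:
    """Optimise the model in place and return it at its best-validation epoch.

    ``metric`` is a hook for the validation metric (default: argmax
    accuracy).  Frozen groups (``model.trainable[g] == False``) receive no
    updates and remain bit-identical.  Deterministic given ``cfg.seed``.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise TrainError("training and validation sets must be non-empty")
    metric = metric or validation_accuracy
    pairs = [pair for g in GROUP_NAMES if model.trainable[g] for pair in model.group_pairs(g)]
    if cfg.max_epochs == 0:
        return model
    if not pairs:
        raise TrainError("no trainable parameter groups")
    optimizer = Adam(pairs, lr=cfg.learning_rate)

    best_acc = -np.inf
    best_snap = None
    best_epoch = -1
    n = len(train_set)
    for epoch in range(cfg.max_epochs):
        rng = np.random.default_rng([int(cfg.seed), epoch])
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            loss = model.train_step(
                train_set.patches[idx], train_set.atlas_vectors[idx],
                train_set.labels[idx], optimizer,
            )
            if not np.isfinite(loss):
                raise TrainError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1
        acc = float(metric(model, val_set))
        model.history["loss"].append(epoch_loss / max(1, n_batches))
        model.history["val_accuracy"].append(acc)
        if acc > best_acc:
            best_acc = acc
            best_epoch = epoch
            best_snap = model.snapshot()
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_snap is not None:
        model.restore(best_snap)
    model.history["best_epoch"] = best_epoch
    return model


def transfer(
    source: ModelState,
    target_train: SampleSet,
    target_val: SampleSet,
    cfg: TransferConfig,
) -> ModelState:
    """Adapt a trained source model to a target domain.

    Returns a new model: conv groups frozen and bit-identical to the source,
    classifier re-initialised (seeded) before optimisation, FC groups
    fine-tuned from their source values at the reduced learning rate.
    """
    model = copy.deepcopy(source)
    model.history = {"loss": [], "val_accuracy": []}
    for g in GROUP_NAMES:
        model.set_trainable(g, True)
    for g in cfg.freeze_groups:
        model.set_trainable(g, False)
    if "classifier" in cfg.reset_groups:
        model.reinit_classifier(cfg.seed)
    for g in cfg.reset_groups:
        if g != "classifier":
            raise ModelError(f"only the classifier group supports reset, got {g!r}")
    train_cfg = replace(cfg.base, learning_rate=cfg.learning_rate, seed=cfg.seed)
    return train(model, target_train, target_val, train_cfg)


def assemble_mixed_set(source_sets: Sequence[SampleSet],
                       target_sets: Sequence[SampleSet]) -> SampleSet:
    """Multiset union of source and target sample sets (mixed-training mode)."""
    sets = list(source_sets) + list(target_sets)
    if not sets:
        raise TrainError("assemble_mixed_set needs at least one sample set")
    return SampleSet.concatenate(sets)
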