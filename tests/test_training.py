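import copy

import numpy as np
import pytest

from subseg.core_io import N_CLASSES
from subseg.model import (CONV_GROUPS, FC_GROUPS, GROUP_NAMES, ModelError,
                          NetworkSpec, build_network,
                          total_parameter_count, trainable_parameter_count)
from subseg.sampling import PATCH_SIZE, SampleSet
from subseg.training import (TrainConfig, TrainError, TransferConfig,
                             assemble_mixed_set, train, transfer)

TINY = NetworkSpec(conv_channels=(2, 2, 2, 2, 2), conv_strides=(2, 2, 2, 2, 1),
                   path_fc_units=4, fusion_fc_units=6, seed=0)


def _toy_set(rng, n=64, separable=False):
    """Two-class set; if separable, class is encoded by the tile sign."""
    labels = rng.integers(0, 2, n).astype(np.int16)
    patches = rng.normal(size=(n, 3, PATCH_SIZE, PATCH_SIZE)).astype(np.float32)
    if separable:
        patches = np.where(labels[:, None, None, None] > 0,
                           np.abs(patches) + 1.0, -np.abs(patches) - 1.0)
    atlas = np.full((n, N_CLASSES), 1.0 / N_CLASSES, dtype=np.float32)
    return SampleSet(patches=patches, atlas_vectors=atlas, labels=labels,
                     voxels=np.zeros((n, 3), dtype=np.int32))


def _params(model):
    return {g: [p.copy() for p in model.group_params(g)] for g in GROUP_NAMES}


class TestEarlyStopping:
    def test_constant_metric_stops_after_patience_plus_one(self, rng):
        """With patience 2 and a flat validation metric the loop runs exactly
        1 (best) + 2 (patience) epochs and restores the first epoch's weights."""
        ss = _toy_set(rng)
        tr, va = ss.select(np.arange(48)), ss.select(np.arange(48, 64))
        epochs_weights = []

        def constant_metric(model, _):
            epochs_weights.append(_params(model))
            return 0.5

        model = build_network(TINY)
        cfg = TrainConfig(max_epochs=50, patience=2, learning_rate=1e-3, seed=1)
        model = train(model, tr, va, cfg, metric=constant_metric)
        assert len(model.history["val_accuracy"]) == 3
        assert model.history["best_epoch"] == 0
        final = _params(model)
        for g in GROUP_NAMES:
            for got, best in zip(final[g], epochs_weights[0][g]):
                np.testing.assert_array_equal(got, best)

    def test_improving_metric_runs_to_max_epochs(self, rng):
        ss = _toy_set(rng)
        tr, va = ss.select(np.arange(48)), ss.select(np.arange(48, 64))
        calls = iter(range(1000))

        model = build_network(TINY)
        cfg = TrainConfig(max_epochs=6, patience=2, learning_rate=1e-3, seed=1)
        model = train(model, tr, va, cfg, metric=lambda m, v: next(calls))
        assert len(model.history["val_accuracy"]) == 6

    def test_best_epoch_is_argmax_of_history(self, rng):
        ss = _toy_set(rng, separable=True)
        tr, va = ss.select(np.arange(48)), ss.select(np.arange(48, 64))
        model = build_network(TINY)
        model = train(model, tr, va,
                      TrainConfig(max_epochs=8, patience=3, learning_rate=1e-3, seed=2))
        hist = model.history["val_accuracy"]
        assert model.history["best_epoch"] == int(np.argmax(hist))
        assert len(hist) <= model.history["best_epoch"] + 3 + 1


class TestTrainBasics:
    def test_separable_set_reaches_full_training_accuracy(self, rng):
        ss = _toy_set(rng, n=96, separable=True)
        tr, va = ss.select(np.arange(72)), ss.select(np.arange(72, 96))
        model = build_network(TINY)
        model = train(model, tr, va,
                      TrainConfig(max_epochs=80, patience=79, learning_rate=1e-2, seed=3))
        probs, _ = model.forward(tr.patches, tr.atlas_vectors, train=False)
        assert (probs.argmax(1) == tr.labels).mean() == 1.0

    def test_reproducible_under_seed(self, rng):
        ss = _toy_set(rng)
        tr, va = ss.select(np.arange(48)), ss.select(np.arange(48, 64))
        cfg = TrainConfig(max_epochs=3, patience=2, learning_rate=1e-3, seed=7)
        m1 = train(build_network(TINY), tr, va, cfg)
        m2 = train(build_network(TINY), tr, va, cfg)
        for g in GROUP_NAMES:
            for p1, p2 in zip(m1.group_params(g), m2.group_params(g)):
                np.testing.assert_array_equal(p1, p2)

    def test_frozen_groups_stay_bit_identical(self, rng):
        ss = _toy_set(rng)
        tr, va = ss.select(np.arange(48)), ss.select(np.arange(48, 64))
        model = build_network(TINY)
        for g in CONV_GROUPS:
            model.set_trainable(g, False)
        before = _params(model)
        model = train(model, tr, va,
                      TrainConfig(max_epochs=3, patience=2, learning_rate=1e-2, seed=4))
        after = _params(model)
        for g in CONV_GROUPS:
            for b, a in zip(before[g], after[g]):
                np.testing.assert_array_equal(b, a)
        assert any(not np.array_equal(b, a)
                   for g in FC_GROUPS for b, a in zip(before[g], after[g]))

    def test_empty_sets_rejected(self, rng):
        ss = _toy_set(rng)
        empty = ss.select(np.arange(0))
        with pytest.raises(TrainError):
            train(build_network(TINY), empty, ss, TrainConfig())


class TestTransferProtocol:
    @pytest.fixture()
    def source(self, rng):
        ss = _toy_set(rng, separable=True)
        tr, va = ss.select(np.arange(48)), ss.select(np.arange(48, 64))
        return train(build_network(TINY), tr, va,
                     TrainConfig(max_epochs=3, patience=2, learning_rate=1e-3, seed=5))

    def test_conv_frozen_classifier_reset_fc_finetuned(self, rng, source):
        ss = _toy_set(rng, n=48, separable=True)
        tr, va = ss.select(np.arange(36)), ss.select(np.arange(36, 48))
        src_params = _params(source)
        cfg = TransferConfig(
            base=TrainConfig(max_epochs=3, patience=2, seed=6), seed=6)
        adapted = transfer(source, tr, va, cfg)
        # conv groups exactly the source's
        for g in CONV_GROUPS:
            for s, a in zip(src_params[g], adapted.group_params(g)):
                np.testing.assert_array_equal(s, a)
        # classifier differs from the source and from a different-seed re-init
        assert not np.array_equal(src_params["classifier"][0],
                                  adapted.classifier.W)
        other = copy.deepcopy(source)
        other.reinit_classifier(seed=99)
        assert not np.array_equal(other.classifier.W, adapted.classifier.W)
        # source model untouched
        for g in GROUP_NAMES:
            for s, p in zip(src_params[g], source.group_params(g)):
                np.testing.assert_array_equal(s, p)

    def test_fewer_trainable_parameters_than_total(self, rng, source):
        ss = _toy_set(rng, n=48)
        tr, va = ss.select(np.arange(36)), ss.select(np.arange(36, 48))
        adapted = transfer(source, tr, va,
                           TransferConfig(base=TrainConfig(max_epochs=1, patience=0, seed=1)))
        conv_sizes = sum(p.size for g in CONV_GROUPS for p in adapted.group_params(g))
        assert trainable_parameter_count(adapted) == \
            total_parameter_count(adapted) - conv_sizes
        assert trainable_parameter_count(adapted) < total_parameter_count(adapted)

    def test_zero_epoch_transfer_is_reset_only(self, rng, source):
        ss = _toy_set(rng, n=48)
        tr, va = ss.select(np.arange(36)), ss.select(np.arange(36, 48))
        src_params = _params(source)
        adapted = transfer(source, tr, va,
                           TransferConfig(base=TrainConfig(max_epochs=0, patience=0, seed=2),
                                          seed=2))
        for g in CONV_GROUPS + FC_GROUPS:
            for s, a in zip(src_params[g], adapted.group_params(g)):
                np.testing.assert_array_equal(s, a)
        assert not np.array_equal(src_params["classifier"][0], adapted.classifier.W)

    def test_group_partition_validated(self):
        with pytest.raises(ModelError):
            TransferConfig(freeze_groups=("conv_axial",))


class TestMixedSets:
    def test_union_counts(self, rng):
        a, b = _toy_set(rng, 10), _toy_set(rng, 14)
        mixed = assemble_mixed_set([a], [b])
        assert len(mixed) == 24
        np.testing.assert_array_equal(
            np.sort(np.concatenate([a.labels, b.labels])), np.sort(mixed.labels))

    def test_empty_target_list_keeps_source(self, rng):
        a = _toy_set(rng, 12)
        mixed = assemble_mixed_set([a], [])
        assert len(mixed) == 12
        np.testing.assert_array_equal(mixed.patches, a.patches)

    def test_duplicates_preserved(self, rng):
        a = _toy_set(rng, 8)
        mixed = assemble_mixed_set([a], [a])
        assert len(mixed) == 16
        np.testing.assert_array_equal(mixed.patches[:8], mixed.patches[8:])
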