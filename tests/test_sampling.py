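import numpy as np
import pytest

from subseg.core_io import AtlasProbability, LabelVolume, N_CLASSES, Volume
from subseg.sampling import (PATCH_SIZE, SampleSet, SamplingError,
                             boundary_shell, build_sample_set,
                             extract_patch_triplet, split_samples,
                             _extract_many)


def _chebyshev_shell_oracle(fg: np.ndarray, radius: int) -> np.ndarray:
    """Brute force: background voxels within Chebyshev distance r of foreground."""
    out = np.zeros_like(fg)
    coords = np.argwhere(fg)
    for idx in np.ndindex(fg.shape):
        if fg[idx]:
            continue
        d = np.abs(coords - np.array(idx)).max(axis=1).min()
        out[idx] = d <= radius
    return out


class TestBoundaryShell:
    def test_single_voxel_radius_one_gives_26_neighbours(self):
        fg = np.zeros((5, 5, 5), dtype=np.int16)
        fg[2, 2, 2] = 1
        shell = boundary_shell(LabelVolume(data=fg), radius=1)
        assert shell.sum() == 26
        assert not shell[2, 2, 2]

    def test_full_grid_has_empty_shell(self):
        fg = np.ones((4, 4, 4), dtype=np.int16)
        assert not boundary_shell(LabelVolume(data=fg), radius=2).any()

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_chebyshev_oracle(self, radius, rng):
        for _ in range(5):
            fg = (rng.random((8, 8, 8)) < 0.08)
            if not fg.any():
                fg[4, 4, 4] = True
            labels = LabelVolume(data=fg.astype(np.int16))
            shell = boundary_shell(labels, radius=radius)
            np.testing.assert_array_equal(shell, _chebyshev_shell_oracle(fg, radius))

    def test_empty_foreground_rejected(self):
        with pytest.raises(SamplingError):
            boundary_shell(LabelVolume(data=np.zeros((4, 4, 4), dtype=np.int16)))


class TestPatchTriplet:
    def test_constant_volume_constant_tiles(self):
        vol = np.full((40, 40, 40), 7.0, dtype=np.float32)
        tiles = extract_patch_triplet(vol, (20, 20, 20))
        assert tiles.shape == (3, PATCH_SIZE, PATCH_SIZE)
        np.testing.assert_array_equal(tiles, 7.0)

    def test_centre_convention(self, rng):
        vol = rng.normal(size=(40, 40, 40)).astype(np.float32)
        i, j, k = 17, 23, 11
        tiles = extract_patch_triplet(vol, (i, j, k))
        half = PATCH_SIZE // 2
        assert tiles[0, half, half] == vol[i, j, k]  # axial
        assert tiles[1, half, half] == vol[i, j, k]  # sagittal
        assert tiles[2, half, half] == vol[i, j, k]  # coronal

    def test_corner_is_quarter_filled(self):
        vol = np.ones((40, 40, 40), dtype=np.float32)
        tiles = extract_patch_triplet(vol, (0, 0, 0))
        half = PATCH_SIZE // 2
        for t in range(3):
            assert tiles[t, half:, half:].all()
            assert not tiles[t, :half, :].any()
            assert not tiles[t, :, :half].any()

    def test_plane_orientation(self, rng):
        """Axial tile comes from the k-slice, sagittal from the i-slice,
        coronal from the j-slice."""
        vol = rng.normal(size=(40, 40, 40)).astype(np.float32)
        i, j, k = 20, 21, 22
        half = PATCH_SIZE // 2
        tiles = extract_patch_triplet(vol, (i, j, k))
        np.testing.assert_array_equal(
            tiles[0], vol[i - half:i + half, j - half:j + half, k])
        np.testing.assert_array_equal(
            tiles[1], vol[i, j - half:j + half, k - half:k + half])
        np.testing.assert_array_equal(
            tiles[2], vol[i - half:i + half, j, k - half:k + half])

    def test_translation_equivariance_interior(self, rng):
        vol = rng.normal(size=(48, 48, 48)).astype(np.float32)
        shifted = np.roll(vol, shift=2, axis=1)
        t1 = extract_patch_triplet(vol, (24, 22, 24))
        t2 = extract_patch_triplet(shifted, (24, 24, 24))
        np.testing.assert_array_equal(t1, t2)

    def test_vectorised_extraction_matches_single(self, rng):
        vol = rng.normal(size=(30, 30, 30)).astype(np.float32)
        voxels = np.array([[0, 0, 0], [29, 29, 29], [15, 3, 27], [7, 16, 2]],
                          dtype=np.int32)
        many = _extract_many(vol, voxels, PATCH_SIZE)
        for row, vox in zip(many, voxels):
            np.testing.assert_array_equal(row, extract_patch_triplet(vol, tuple(vox)))

    def test_outside_grid_rejected(self):
        with pytest.raises(SamplingError):
            extract_patch_triplet(np.zeros((10, 10, 10)), (10, 0, 0))


def _toy_inputs(rng, shape=(20, 20, 20)):
    labels = np.zeros(shape, dtype=np.int16)
    labels[8:12, 8:12, 8:12] = 1
    labels[3:5, 3:5, 3:5] = 2
    lab = LabelVolume(data=labels)
    vol = Volume(data=rng.normal(size=shape).astype(np.float32),
                 mask=np.ones(shape, dtype=bool))
    probs = np.full(shape + (N_CLASSES,), 1.0 / N_CLASSES, dtype=np.float32)
    return vol, lab, AtlasProbability(data=probs)


class TestBuildSampleSet:
    def test_policy_all_counts(self, rng):
        vol, lab, atlas = _toy_inputs(rng)
        ss = build_sample_set(vol, lab, atlas, negatives="all")
        fg = int((lab.data > 0).sum())
        shell = int(boundary_shell(lab, 5).sum())
        assert len(ss) == fg + shell
        assert ss.class_counts[0] == shell

    def test_policy_balanced_and_deterministic(self, rng):
        vol, lab, atlas = _toy_inputs(rng)
        s1 = build_sample_set(vol, lab, atlas, negatives="balanced", seed=7)
        s2 = build_sample_set(vol, lab, atlas, negatives="balanced", seed=7)
        assert s1.class_counts[0] == s1.class_counts[1:].sum()
        np.testing.assert_array_equal(s1.voxels, s2.voxels)
        np.testing.assert_array_equal(s1.patches, s2.patches)

    def test_negatives_exactly_shell_voxels(self, rng):
        vol, lab, atlas = _toy_inputs(rng, shape=(16, 16, 16))
        ss = build_sample_set(vol, lab, atlas, negatives="all")
        shell = boundary_shell(lab, 5)
        for n in range(len(ss)):
            i, j, k = ss.voxels[n]
            if ss.labels[n] == 0:
                assert shell[i, j, k]
            else:
                assert lab.data[i, j, k] == ss.labels[n]

    def test_atlas_vector_taken_at_voxel(self, rng):
        vol, lab, _ = _toy_inputs(rng)
        probs = rng.random(lab.shape + (N_CLASSES,)).astype(np.float32)
        probs /= probs.sum(-1, keepdims=True)
        atlas = AtlasProbability(data=probs)
        ss = build_sample_set(vol, lab, atlas, negatives="all")
        for n in [0, len(ss) // 2, len(ss) - 1]:
            i, j, k = ss.voxels[n]
            np.testing.assert_array_equal(ss.atlas_vectors[n], probs[i, j, k])

    def test_max_samples_cap_with_floor(self, rng):
        vol, lab, atlas = _toy_inputs(rng)
        ss = build_sample_set(vol, lab, atlas, negatives="all", max_samples=30,
                              min_per_class=5, seed=1)
        assert len(ss) <= 30
        present = np.nonzero(ss.class_counts)[0]
        for c in (0, 1, 2):
            assert c in present and ss.class_counts[c] >= 5

    def test_missing_atlas_rejected(self, rng):
        vol, lab, _ = _toy_inputs(rng)
        with pytest.raises(SamplingError, match="atlas"):
            build_sample_set(vol, lab, None)

    def test_hdf5_round_trip(self, tmp_path, rng):
        vol, lab, atlas = _toy_inputs(rng)
        ss = build_sample_set(vol, lab, atlas, negatives="balanced", seed=3,
                              subject="toy")
        ss.save(tmp_path / "s.h5")
        back = SampleSet.load(tmp_path / "s.h5")
        np.testing.assert_array_equal(back.patches, ss.patches)
        np.testing.assert_array_equal(back.labels, ss.labels)
        np.testing.assert_array_equal(back.voxels, ss.voxels)
        assert back.subjects == ["toy"]


class TestSplitSamples:
    def _set(self, rng, n):
        return SampleSet(
            patches=rng.normal(size=(n, 3, PATCH_SIZE, PATCH_SIZE)).astype(np.float32),
            atlas_vectors=np.full((n, N_CLASSES), 1.0 / N_CLASSES, dtype=np.float32),
            labels=rng.integers(0, 15, n).astype(np.int16),
            voxels=rng.integers(0, 20, (n, 3)).astype(np.int32),
        )

    def test_75_25_proportions(self, rng):
        tr, va = split_samples(self._set(rng, 100), 0.75, seed=0)
        assert len(tr) == 75 and len(va) == 25

    def test_deterministic_and_exhaustive(self, rng):
        ss = self._set(rng, 97)
        tr1, va1 = split_samples(ss, seed=5)
        tr2, va2 = split_samples(ss, seed=5)
        np.testing.assert_array_equal(tr1.voxels, tr2.voxels)
        # union of the two parts is the original multiset of rows
        all_labels = np.sort(np.concatenate([tr1.labels, va1.labels]))
        np.testing.assert_array_equal(all_labels, np.sort(ss.labels))
        assert len(tr1) + len(va1) == 97

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(SamplingError):
            split_samples(self._set(rng, 3))


class TestSampleSetOps:
    def test_concatenate_preserves_multiset(self, rng):
        a = TestSplitSamples()._set(rng, 10)
        b = TestSplitSamples()._set(rng, 15)
        both = SampleSet.concatenate([a, b])
        assert len(both) == 25
        np.testing.assert_array_equal(both.patches[:10], a.patches)
        np.testing.assert_array_equal(both.patches[10:], b.patches)

    def test_subsample_stratified(self, rng):
        ss = TestSplitSamples()._set(rng, 200)
        sub = ss.subsample(50, seed=2)
        assert len(sub) <= 50
        # every class with samples keeps at least one
        for c in np.nonzero(ss.class_counts)[0]:
            assert sub.class_counts[c] >= 1
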