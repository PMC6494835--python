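from itertools import product

import numpy as np
import pytest
from scipy import stats

from subseg.core_io import LabelVolume
from subseg.evaluation import (EvaluationError, EvalRecord, dsc,
                               structure_dsc, weighted_dsc,
                               wilcoxon_signed_rank, records_to_table)


def _exhaustive_wilcoxon_p(diff: np.ndarray) -> tuple[float, float]:
    """Oracle: two-sided exact p by enumerating all 2^n sign assignments of
    the observed mid-ranks."""
    diff = diff[diff != 0]
    n = len(diff)
    ranks = stats.rankdata(np.abs(diff))
    w_pos = ranks[diff > 0].sum()
    w_obs = min(w_pos, ranks.sum() - w_pos)
    count = 0
    for signs in product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_plus, ranks.sum() - w_plus)
        if w <= w_obs + 1e-12:
            count += 1
    return w_obs, count / 2**n


class TestDice:
    def test_identical_masks_give_one(self, rng):
        m = rng.random((8, 8, 8)) < 0.3
        m[0, 0, 0] = True
        assert dsc(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[0], b[3] = True, True
        assert dsc(a, b) == 0.0

    def test_half_overlap_oracle(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, :4] = True           # |a| = 4
        b[0, 0, 2:4] = True
        b[0, 1, :2] = True           # |b| = 4, overlap 2
        assert dsc(a, b) == pytest.approx(0.5)

    def test_symmetric(self, rng):
        a = rng.random((8, 8, 8)) < 0.3
        b = rng.random((8, 8, 8)) < 0.3
        a[0, 0, 0] = True
        assert dsc(a, b) == dsc(b, a)

    def test_matches_voxel_count_oracle_on_random_masks(self, rng):
        for _ in range(100):
            a = rng.random((8, 8, 8)) < rng.uniform(0.05, 0.5)
            b = rng.random((8, 8, 8)) < rng.uniform(0.05, 0.5)
            if not (a.any() or b.any()):
                continue
            expected = 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
            got = dsc(a, b)
            assert got == expected
            assert 0.0 <= got <= 1.0

    def test_both_empty_rejected(self):
        z = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(EvaluationError):
            dsc(z, z)


class TestStructureDsc:
    def test_perfect_prediction(self, rng):
        data = rng.integers(0, 15, (10, 10, 10)).astype(np.int16)
        for cls in range(15):
            data.ravel()[cls] = cls  # ensure every class present
        lab = LabelVolume(data=data)
        rec = structure_dsc(lab, lab)
        assert all(rec.per_structure[c] == 1.0 for c in range(1, 15))
        assert rec.average == 1.0

    def test_all_background_prediction_scores_zero(self, rng):
        gt = LabelVolume(data=rng.integers(0, 15, (10, 10, 10)).astype(np.int16))
        pred = LabelVolume(data=np.zeros((10, 10, 10), dtype=np.int16))
        rec = structure_dsc(pred, gt)
        assert all(rec.per_structure[c] == 0.0 for c in rec.defined_classes)

    def test_left_right_swap_failure_mode(self):
        """Swapping the thalami zeroes both structure scores even though the
        union overlap is perfect — the hemisphere-swap failure signature."""
        gt = np.zeros((16, 16, 16), dtype=np.int16)
        gt[2:6, 6:10, 6:10] = 1    # left thalamus
        gt[10:14, 6:10, 6:10] = 2  # right thalamus
        swapped = np.zeros_like(gt)
        swapped[2:6, 6:10, 6:10] = 2
        swapped[10:14, 6:10, 6:10] = 1
        rec = structure_dsc(LabelVolume(data=swapped), LabelVolume(data=gt))
        assert rec.per_structure[1] == 0.0 and rec.per_structure[2] == 0.0
        assert dsc(swapped > 0, gt > 0) == 1.0

    def test_absent_structures_excluded_from_average(self):
        gt = np.zeros((8, 8, 8), dtype=np.int16)
        gt[2:4] = 1
        rec = structure_dsc(LabelVolume(data=gt), LabelVolume(data=gt))
        assert rec.defined_classes == [1]
        assert np.isnan(rec.per_structure[2])
        assert rec.average == 1.0


class TestWeightedDsc:
    def test_equal_scores_invariant_to_volumes(self):
        rec = EvalRecord("s", {1: 0.7, 2: 0.7, 3: 0.7},
                         {1: 1000, 2: 50, 3: 3})
        assert weighted_dsc(rec) == pytest.approx(0.7)

    def test_two_structure_oracle(self):
        rec = EvalRecord("s", {1: 0.9, 2: 0.5}, {1: 100, 2: 10})
        expected = (0.9 / 100 + 0.5 / 10) / (1 / 100 + 1 / 10)
        assert weighted_dsc(rec) == pytest.approx(expected, abs=1e-9)
        assert weighted_dsc(rec) == pytest.approx(0.5363636363636364, abs=1e-9)

    def test_weighted_below_mean_when_small_structures_score_lower(self, rng):
        for _ in range(20):
            n = rng.integers(3, 8)
            vols = np.sort(rng.integers(10, 1000, n))[::-1]
            scores = np.sort(rng.random(n))[::-1]  # smaller structure, lower score
            rec = EvalRecord("s", {i + 1: float(s) for i, s in enumerate(scores)},
                             {i + 1: int(v) for i, v in enumerate(vols)})
            brute = float(np.sum(scores / vols) / np.sum(1.0 / vols))
            assert weighted_dsc(rec) == pytest.approx(brute, abs=1e-12)
            assert weighted_dsc(rec) <= rec.average + 1e-12

    def test_zero_volume_rejected(self):
        rec = EvalRecord("s", {1: 0.5, 2: 0.6}, {1: 10, 2: 0})
        with pytest.raises(EvaluationError):
            weighted_dsc(rec)


class TestWilcoxon:
    def test_constant_shift_n6_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x + 1.0
        stat, p = wilcoxon_signed_rank(x, y)
        assert stat == 0.0
        assert p == pytest.approx(2.0 / 64.0)

    def test_symmetry_under_swap(self, rng):
        x = rng.normal(size=8)
        y = x + rng.normal(size=8)
        s1, p1 = wilcoxon_signed_rank(x, y)
        s2, p2 = wilcoxon_signed_rank(y, x)
        assert s1 == s2 and p1 == pytest.approx(p2)

    @pytest.mark.parametrize("n", [5, 6, 8, 10])
    def test_exact_branch_matches_enumeration(self, n, rng):
        for _ in range(5):
            diff = rng.normal(size=n)
            diff[diff == 0] = 0.5
            x = rng.normal(size=n)
            y = x + diff
            w_oracle, p_oracle = _exhaustive_wilcoxon_p(diff)
            stat, p = wilcoxon_signed_rank(x, y)
            assert stat == pytest.approx(w_oracle)
            assert p == pytest.approx(p_oracle)

    def test_ties_use_midranks_and_match_enumeration(self):
        diff = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0, -2.0])
        x = np.zeros(7)
        y = diff
        w_oracle, p_oracle = _exhaustive_wilcoxon_p(diff)
        stat, p = wilcoxon_signed_rank(x, y)
        assert stat == pytest.approx(w_oracle)
        assert p == pytest.approx(p_oracle)

    def test_matches_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(size=12) * 0.5
        stat, p = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(y, x, alternative="two-sided", method="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation_close_to_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + 0.3 + rng.normal(size=40) * 0.5
        _, p = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(y, x, alternative="two-sided", method="approx",
                             correction=True)
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_all_zero_differences_rejected(self):
        x = np.ones(6)
        with pytest.raises(EvaluationError):
            wilcoxon_signed_rank(x, x)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(EvaluationError):
            wilcoxon_signed_rank([1, 2, 3, 4], [2, 3, 4, 5])


class TestReportTable:
    def test_table_layout(self):
        rec = EvalRecord("sub-0", {c: 0.8 for c in range(1, 15)},
                         {c: 100 for c in range(1, 15)})
        table = records_to_table([rec])
        assert list(table.columns)[:3] == ["subject", "Tha.L", "Tha.R"]
        assert list(table.columns)[-2:] == ["Avg.", "wAvg."]
        assert table.loc[0, "Avg."] == pytest.approx(0.8)
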