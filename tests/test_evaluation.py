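"""Metrics, stratified aggregation and cross-validation splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cscseg.evaluation import (classify_axis, dice, evaluate_results, iou,
                               make_folds, summarize)
from cscseg.geometry import CropRecord
from cscseg.inference import CSCResult


def _mask(shape, ones):
    m = np.zeros(shape, dtype=np.uint8)
    for (y, x) in ones:
        m[y, x] = 1
    return m


class TestIoUDice:
    def test_identical_masks(self):
        m = _mask((4, 4), [(0, 0), (1, 1), (2, 2)])
        assert iou(m, m) == 1.0 and dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = _mask((4, 4), [(0, 0)])
        b = _mask((4, 4), [(3, 3)])
        assert iou(a, b) == 0.0 and dice(a, b) == 0.0

    def test_formula_arithmetic(self):
        # TP=2, FP=0, FN=2
        truth = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (1, 1)])
        pred = _mask((4, 4), [(0, 0), (0, 1)])
        assert iou(pred, truth) == 0.5
        assert dice(pred, truth) == pytest.approx(2 / 3)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert iou(z, z) == 1.0 and dice(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_dice_iou_identity_on_random_pairs(self, rng):
        for _ in range(200):
            a = (rng.random((16, 16)) > 0.6).astype(np.uint8)
            b = (rng.random((16, 16)) > 0.6).astype(np.uint8)
            i, d = iou(a, b), dice(a, b)
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)
            assert d >= i

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_matches_counting_formula(self, tp, fp, fn):
        # build a mask pair realizing exactly (TP, FP, FN) and check both metrics
        n = tp + fp + fn + 1
        pred = np.zeros(n, dtype=np.uint8)
        truth = np.zeros(n, dtype=np.uint8)
        pred[:tp] = truth[:tp] = 1
        pred[tp:tp + fp] = 1
        truth[tp + fp:tp + fp + fn] = 1
        denom = tp + fp + fn
        expected_iou = 1.0 if denom == 0 else tp / denom
        expected_dice = 1.0 if denom == 0 else 2 * tp / (2 * tp + fp + fn)
        assert iou(pred, truth) == pytest.approx(expected_iou, abs=1e-12)
        assert dice(pred, truth) == pytest.approx(expected_dice, abs=1e-12)


class TestClassifyAxis:
    @pytest.mark.parametrize("angle,group", [
        (0, "apical"), (29.9, "apical"), (30, "apical"), (31, "non-apical"),
        (45, "non-apical"), (90, "non-apical"), (149, "non-apical"),
        (150, "apical"), (170, "apical"), (179, "apical"),
    ])
    def test_fold_rule(self, angle, group):
        assert classify_axis(angle) == group


def _result(detected, clip_id="c", shape=(20, 20), window=(4, 16, 4, 16)):
    if not detected:
        return CSCResult(detected=False, clip_id=clip_id,
                         binary_crop=np.zeros((8, 8), dtype=np.uint8),
                         binary_original=np.zeros(shape, dtype=np.uint8))
    rec = CropRecord(window, (shape[1], shape[0]), (12, 12))
    binary_original = np.zeros(shape, dtype=np.uint8)
    binary_original[6:12, 6:12] = 1
    binary_crop = np.zeros((12, 12), dtype=np.uint8)
    binary_crop[2:8, 2:8] = 1
    return CSCResult(detected=True, crop_record=rec, clip_id=clip_id,
                     binary_crop=binary_crop, binary_original=binary_original)


class TestEvaluateResults:
    def _label(self, angle=0.0, phase="systole"):
        return dict(axis_angle_deg=angle, phase=phase)

    def test_failure_scores_zero(self):
        truth = np.zeros((20, 20), dtype=np.uint8)
        truth[5, 5] = 1
        df = evaluate_results([_result(False)], [truth], [self._label()])
        assert (df.iou == 0).all() and (df.dice == 0).all()
        assert not df.detected.any()

    def test_mean_includes_failures_as_zero(self):
        truth = np.zeros((20, 20), dtype=np.uint8)
        truth[6:12, 6:12] = 1
        results = [_result(True, "a"), _result(False, "b")]
        df = evaluate_results(results, [truth, truth],
                              [self._label(), self._label()])
        s = summarize(df)
        orig = s[s.space == "original"].iloc[0]
        perfect = df[(df.clip_id == "a") & (df.space == "original")].iou.iloc[0]
        assert orig.miou == pytest.approx(perfect / 2)
        assert orig.n_failed == 1

    def test_all_failures_zero_aggregate(self):
        truth = np.ones((20, 20), dtype=np.uint8)
        df = evaluate_results([_result(False), _result(False)], [truth, truth],
                              [self._label(), self._label()])
        s = summarize(df)
        assert (s.miou == 0).all() and (s.mdice == 0).all()

    def test_stratified_means_recombine(self, rng):
        results, truths, labels = [], [], []
        for k in range(12):
            truth = (rng.random((20, 20)) > 0.7).astype(np.uint8)
            results.append(_result(bool(k % 3), clip_id=f"c{k}"))
            truths.append(truth)
            labels.append(self._label(angle=float(rng.uniform(0, 180)),
                                      phase="systole" if k % 2 else "diastole"))
        df = evaluate_results(results, truths, labels)
        total = summarize(df)
        by_axis = summarize(df, by=["axis_group"])
        for space in ("crop", "original"):
            tot = total[total.space == space].iloc[0]
            grp = by_axis[by_axis.space == space]
            recombined = (grp.miou * grp.n).sum() / grp.n.sum()
            assert recombined == pytest.approx(tot.miou, abs=1e-12)

    def test_mean_order_invariance(self, rng):
        truths = [(rng.random((20, 20)) > 0.7).astype(np.uint8) for _ in range(6)]
        results = [_result(True, f"c{k}") for k in range(6)]
        labels = [self._label() for _ in range(6)]
        a = summarize(evaluate_results(results, truths, labels))
        perm = [3, 1, 5, 0, 2, 4]
        b = summarize(evaluate_results([results[i] for i in perm],
                                       [truths[i] for i in perm],
                                       [labels[i] for i in perm]))
        pd.testing.assert_frame_equal(a, b)

    def test_parallel_list_validation(self):
        with pytest.raises(ValueError):
            evaluate_results([_result(True)], [], [])


class TestMakeFolds:
    def test_cohort_arithmetic(self):
        ids = [f"img{i}" for i in range(615)]
        folds = make_folds(ids, seed=0)
        assert len(folds) == 3
        for f in folds:
            assert len(f.test_ids) == 205
            assert len(f.train_ids) + len(f.val_ids) == 410
            assert len(f.val_ids) == 82
            assert len(f.train_ids) == 328
            assert not (set(f.train_ids) | set(f.val_ids)) & set(f.test_ids)
            assert not set(f.train_ids) & set(f.val_ids)

    def test_test_sets_partition_cohort(self):
        ids = list(range(100))
        folds = make_folds(ids, seed=3)
        all_test = [i for f in folds for i in f.test_ids]
        assert sorted(all_test) == ids

    def test_seeded_reproducibility(self):
        ids = list(range(30))
        assert make_folds(ids, seed=5) == make_folds(ids, seed=5)
        assert make_folds(ids, seed=5) != make_folds(ids, seed=6)

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            make_folds([1, 2], seed=0)

    def test_grouped_folds_keep_groups_together(self):
        ids = [f"frame{i}" for i in range(40)]
        groups = [f"video{i // 4}" for i in range(40)]  # 10 videos of 4 frames
        by_group = {g: {i for i, gg in zip(ids, groups) if gg == g}
                    for g in set(groups)}
        folds = make_folds(ids, seed=9, groups=groups)
        all_test = []
        for f in folds:
            parts = [set(f.train_ids), set(f.val_ids), set(f.test_ids)]
            assert set().union(*parts) == set(ids)
            for members in by_group.values():
                # every video lands wholly inside one partition
                assert sum(bool(members & p) for p in parts) == 1
            all_test.extend(f.test_ids)
        assert sorted(all_test) == sorted(ids)
        assert make_folds(ids, 9, groups=groups) == make_folds(ids, 9, groups=groups)
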