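"""Detection/segmentation scoring and the Monte-Carlo rank-sum comparison."""

import numpy as np
import pytest

from conftest import make_disk
from sevseg.evaluate import (AOGM_WEIGHTS, Matching, det_score, match,
                             mc_wilcoxon, seg_score)
from sevseg.postprocess import LabeledMask

PX = 1.56


def lm(labels):
    return LabeledMask(labels=np.asarray(labels, dtype=np.int32),
                       pixel_size_nm=PX)


def random_disk_mask(rng, shape=(128, 128), max_objects=10):
    labels = np.zeros(shape, np.int32)
    n = rng.integers(0, max_objects + 1)
    k = 0
    for _ in range(n):
        r = rng.integers(5, 15)
        c = (rng.integers(r, shape[0] - r), rng.integers(r, shape[1] - r))
        d = make_disk(shape, c, r) & (labels == 0)
        if d.sum() > 10:
            k += 1
            labels[d] = k
    return labels


def bruteforce_det_seg(gt, pred):
    """Independent oracle: enumerate all label overlaps directly."""
    gt_labels = [g for g in np.unique(gt) if g > 0]
    pred_labels = [p for p in np.unique(pred) if p > 0]
    pairs = {}
    jacc = {}
    claimed = {}
    for g in gt_labels:
        gm = gt == g
        partner = None
        for p in pred_labels:
            inter = (gm & (pred == p)).sum()
            if inter * 2 > gm.sum():
                partner = p
        pairs[g] = partner
        if partner is None:
            jacc[g] = 0.0
        else:
            pm = pred == partner
            jacc[g] = (gm & pm).sum() / (gm | pm).sum()
            claimed.setdefault(partner, []).append(g)
    tp = sum(1 for v in pairs.values() if v is not None)
    fn = len(gt_labels) - tp
    fp = len([p for p in pred_labels if p not in claimed])
    ns = sum(len(v) - 1 for v in claimed.values())
    aogm_d = 5 * ns + 10 * fn + 1 * fp
    aogm_0 = 10 * len(gt_labels)
    if aogm_0 == 0:
        det = 1.0 if aogm_d == 0 else 0.0
    else:
        det = 1 - min(aogm_d, aogm_0) / aogm_0
    seg = np.mean(list(jacc.values())) if jacc else None
    return det, seg


class TestMatch:
    def test_identical_masks_fully_matched(self):
        labels = np.zeros((80, 80), np.int32)
        labels[make_disk(labels.shape, (30, 30), 10)] = 1
        labels[make_disk(labels.shape, (60, 60), 8)] = 2
        m = match(lm(labels), lm(labels))
        assert m.pairs == {1: 1, 2: 2}
        assert m.fp_labels == [] and m.ns_groups == {}
        assert all(j == 1.0 for j in m.jaccard.values())

    def test_forty_percent_overlap_not_a_detection(self):
        gt = np.zeros((40, 40), np.int32)
        gt[10:20, 10:20] = 1                       # 100 px
        pred = np.zeros_like(gt)
        pred[10:14, 10:20] = 1                     # covers 40 px of gt
        m = match(lm(gt), lm(pred))
        assert m.pairs == {1: None}
        assert m.fp_labels == [1]

    def test_single_blob_over_two_objects_is_ns_event(self):
        gt = np.zeros((60, 100), np.int32)
        gt[20:40, 10:40] = 1
        gt[20:40, 60:90] = 2
        pred = np.zeros_like(gt)
        pred[18:42, 5:95] = 1                      # covers both entirely
        m = match(lm(gt), lm(pred))
        assert m.ns_groups == {1: [1, 2]}
        assert m.fp_labels == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match(lm(np.zeros((4, 4))), lm(np.zeros((5, 4))))


class TestDetScore:
    def test_empty_prediction_scores_zero(self):
        gt = np.zeros((60, 60), np.int32)
        gt[make_disk(gt.shape, (30, 30), 10)] = 1
        rep = det_score(match(lm(gt), lm(np.zeros_like(gt))))
        assert rep.AOGM_D == rep.AOGM_0 == 10.0
        assert rep.DET == 0.0

    def test_perfect_prediction_scores_one(self):
        gt = np.zeros((60, 60), np.int32)
        gt[make_disk(gt.shape, (30, 30), 10)] = 1
        rep = det_score(match(lm(gt), lm(gt)))
        assert rep.AOGM_D == 0.0 and rep.DET == 1.0

    def test_hand_arithmetic_with_ctc_weights(self):
        # 10 GT, 8 TP, 2 FN, 3 FP, 0 NS -> DET = 1 - 23/100 = 0.77
        m = Matching(pairs={g: (g if g <= 8 else None) for g in range(1, 11)},
                     fp_labels=[90, 91, 92], ns_groups={},
                     jaccard={g: 1.0 for g in range(1, 11)},
                     n_gt=10, n_pred=11)
        rep = det_score(m)
        assert rep.TP == 8 and rep.FN == 2 and rep.FP == 3 and rep.NS == 0
        assert rep.AOGM_D == 23.0 and rep.AOGM_0 == 100.0
        assert rep.DET == pytest.approx(0.77)
        assert rep.fp_ratio == pytest.approx(3 / 11)

    def test_det_invariant_to_label_permutation(self, rng):
        gt = random_disk_mask(rng)
        pred = random_disk_mask(rng)
        rep = det_score(match(lm(gt), lm(pred)))
        perm = np.concatenate([[0], rng.permutation(gt.max()) + 1])
        gt_perm = perm[gt]
        rep_perm = det_score(match(lm(gt_perm), lm(pred)))
        assert rep_perm.DET == pytest.approx(rep.DET)

    def test_extra_false_positive_lowers_det_and_raises_ratio(self):
        gt = np.zeros((100, 100), np.int32)
        gt[make_disk(gt.shape, (30, 30), 10)] = 1
        pred = gt.copy()
        base = det_score(match(lm(gt), lm(pred)))
        pred_fp = pred.copy()
        pred_fp[make_disk(gt.shape, (75, 75), 8)] = 2
        worse = det_score(match(lm(gt), lm(pred_fp)))
        assert worse.DET < base.DET
        assert worse.fp_ratio > base.fp_ratio


class TestSegScore:
    def test_identity_gives_unit_scores(self):
        gt = np.zeros((60, 60), np.int32)
        gt[make_disk(gt.shape, (30, 30), 12)] = 1
        rep = seg_score(match(lm(gt), lm(gt)))
        assert rep.SEG == rep.SEG_star == 1.0

    def test_nested_prediction_gives_area_ratio_jaccard(self):
        gt = np.zeros((60, 60), np.int32)
        gt[20:40, 10:50] = 1                       # 800 px
        pred = np.zeros_like(gt)
        pred[20:40, 10:31] = 1                     # 420 px, fully inside gt
        rep = seg_score(match(lm(gt), lm(pred)))
        assert rep.SEG == pytest.approx(420 / 800)
        assert rep.SEG_star == pytest.approx(420 / 800)

    def test_exactly_half_overlap_is_not_a_majority(self):
        gt = np.zeros((60, 60), np.int32)
        gt[20:40, 10:50] = 1                       # 800 px
        pred = np.zeros_like(gt)
        pred[20:40, 10:30] = 1                     # exactly 400 px of gt
        rep = seg_score(match(lm(gt), lm(pred)))
        assert rep.SEG == 0.0

    def test_undetected_object_counts_zero_only_in_seg(self):
        m = Matching(pairs={1: 1, 2: None}, fp_labels=[], ns_groups={},
                     jaccard={1: 0.8, 2: 0.0}, n_gt=2, n_pred=1)
        rep = seg_score(m)
        assert rep.SEG == pytest.approx(0.4)
        assert rep.SEG_star == pytest.approx(0.8)

    def test_no_gt_objects_rejected(self):
        m = match(lm(np.zeros((8, 8))), lm(np.zeros((8, 8))))
        with pytest.raises(ValueError):
            seg_score(m)

    def test_seg_never_exceeds_seg_star(self, rng):
        for _ in range(10):
            gt = random_disk_mask(rng)
            pred = random_disk_mask(rng)
            if gt.max() == 0:
                continue
            rep = seg_score(match(lm(gt), lm(pred)))
            assert rep.SEG <= rep.SEG_star + 1e-12


class TestOracleEquivalence:
    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(25):
            gt = random_disk_mask(rng)
            pred = random_disk_mask(rng)
            m = match(lm(gt), lm(pred))
            det = det_score(m).DET
            det_bf, seg_bf = bruteforce_det_seg(gt, pred)
            assert det == pytest.approx(det_bf, abs=1e-12)
            if seg_bf is not None:
                assert seg_score(m).SEG == pytest.approx(seg_bf, abs=1e-12)


class TestMCWilcoxon:
    def test_fold_arithmetic_large_sample(self, rng):
        a = rng.normal(size=346)
        b = rng.normal(size=400)
        res = mc_wilcoxon(a, b, seed=0)
        assert res.fold_size == 30
        assert res.folds == 115          # floor(10 * 346 / 30)

    def test_fold_arithmetic_small_sample(self, rng):
        a = rng.normal(size=21)
        b = rng.normal(size=50)
        res = mc_wilcoxon(a, b, seed=0)
        assert res.fold_size == 14       # floor(2/3 * 21)
        assert res.folds == 15           # floor(10 * 21 / 14)

    def test_deterministic_given_seed(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        assert mc_wilcoxon(a, b, seed=5).mean_p == mc_wilcoxon(a, b, seed=5).mean_p

    def test_shifted_distributions_give_small_p(self, rng):
        a = rng.normal(0.0, 1.0, size=200)
        b = rng.normal(2.0, 1.0, size=200)
        assert mc_wilcoxon(a, b, seed=0).mean_p < 0.01

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mc_wilcoxon([1.0, 2.0], [1.0, 2.0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mc_wilcoxon([], [1.0])
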