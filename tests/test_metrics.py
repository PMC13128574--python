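"""Metric oracles: brute-force pair/entropy computations on tiny labelings."""

import numpy as np
import pytest

from anisoseg.exceptions import DimensionError, UndefinedMetricError
from anisoseg.metrics import ap75, arand, contingency, evaluate_labels, voi


def brute_force_voi(seg, gt, base=2.0):
    """Conditional entropies from the empirical joint distribution."""
    seg, gt = np.ravel(seg), np.ravel(gt)
    n = seg.size
    pairs = {}
    for s, g in zip(seg, gt):
        pairs[(g, s)] = pairs.get((g, s), 0) + 1
    pg, ps = {}, {}
    for (g, s), c in pairs.items():
        pg[g] = pg.get(g, 0) + c
        ps[s] = ps.get(s, 0) + c
    h_split = h_merge = 0.0
    for (g, s), c in pairs.items():
        p = c / n
        h_split -= p * np.log(p / (pg[g] / n)) / np.log(base)
        h_merge -= p * np.log(p / (ps[s] / n)) / np.log(base)
    return h_split, h_merge


def brute_force_arand(seg, gt):
    """O(n^2) loop over unordered voxel pairs."""
    seg, gt = np.ravel(seg), np.ravel(gt)
    keep = gt > 0
    seg, gt = seg[keep], gt[keep]
    n = seg.size
    both = seg_pairs = gt_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            ss = seg[i] == seg[j]
            gg = gt[i] == gt[j]
            both += ss and gg
            seg_pairs += ss
            gt_pairs += gg
    if seg_pairs == 0 and gt_pairs == 0:
        return 0.0
    prec = both / seg_pairs if seg_pairs else (1.0 if both == 0 else 0.0)
    rec = both / gt_pairs if gt_pairs else (1.0 if both == 0 else 0.0)
    if prec + rec == 0:
        return 1.0
    return 1.0 - 2 * prec * rec / (prec + rec)


class TestContingency:
    def test_identical_labelings_are_diagonal(self):
        lab = np.array([[[1, 1], [2, 3]]])
        t = contingency(lab, lab)
        d = t.dense()
        assert np.all(d == np.diag(np.diag(d)))

    def test_toy_enumeration(self):
        gt = np.array([1, 1, 2, 2]).reshape(1, 1, 4)
        seg = np.array([1, 1, 1, 2]).reshape(1, 1, 4)
        assert contingency(seg, gt).as_dict() == {(1, 1): 2, (2, 1): 1, (2, 2): 1}

    def test_permuting_seg_ids_permutes_columns_only(self):
        gt = np.array([[[1, 1, 2, 2]]])
        seg = np.array([[[3, 3, 4, 4]]])
        seg_perm = np.array([[[4, 4, 3, 3]]])
        a = contingency(seg, gt).dense()
        b = contingency(seg_perm, gt).dense()
        np.testing.assert_array_equal(a, b[:, ::-1])

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            contingency(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestVoi:
    def test_relabeling_gives_zero(self):
        gt = np.array([[[1, 1, 2, 2, 3]]])
        seg = np.array([[[7, 7, 5, 5, 9]]])
        assert voi(seg, gt) == pytest.approx((0.0, 0.0, 0.0))

    def test_equal_split_is_one_bit(self):
        gt = np.array([[[1, 1, 1, 1]]])
        seg = np.array([[[1, 1, 2, 2]]])
        vs, vm, vt = voi(seg, gt, log_base=2.0)
        assert (vs, vm, vt) == pytest.approx((1.0, 0.0, 1.0))

    def test_equal_merge_is_one_bit(self):
        gt = np.array([[[1, 1, 2, 2]]])
        seg = np.array([[[1, 1, 1, 1]]])
        vs, vm, vt = voi(seg, gt, log_base=2.0)
        assert (vs, vm, vt) == pytest.approx((0.0, 1.0, 1.0))

    def test_empty_volume_undefined(self):
        with pytest.raises(UndefinedMetricError):
            voi(np.zeros((0,), dtype=int), np.zeros((0,), dtype=int))

    def test_matches_brute_force_on_random_labelings(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            gt = rng.integers(0, 5, n)
            seg = rng.integers(0, 5, n)
            got = voi(seg, gt)
            expect = brute_force_voi(seg, gt)
            assert got[0] == pytest.approx(expect[0], abs=1e-10)
            assert got[1] == pytest.approx(expect[1], abs=1e-10)


class TestArand:
    def test_relabeled_perfect_is_zero(self):
        gt = np.array([[[1, 1, 2, 2, 0]]])
        seg = np.array([[[5, 5, 3, 3, 1]]])
        assert arand(seg, gt) == pytest.approx(0.0)

    def test_single_blob_vs_two_objects_positive(self):
        gt = np.array([[[1, 1, 2, 2]]])
        seg = np.ones((1, 1, 4), dtype=int)
        assert arand(seg, gt) > 0.0

    def test_matches_brute_force_on_random_labelings(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            gt = rng.integers(0, 4, n)
            seg = rng.integers(0, 4, n)
            if not np.any(gt > 0):
                continue
            assert arand(seg, gt) == pytest.approx(brute_force_arand(seg, gt),
                                                   abs=1e-10)

    def test_all_background_undefined(self):
        with pytest.raises(UndefinedMetricError):
            arand(np.ones((1, 1, 3), dtype=int), np.zeros((1, 1, 3), dtype=int))

    def test_label_permutation_invariance(self, rng):
        gt = rng.integers(0, 4, (3, 4, 4))
        seg = rng.integers(0, 4, (3, 4, 4))
        perm = {0: 0, 1: 3, 2: 1, 3: 2}
        seg_p = np.vectorize(perm.get)(seg)
        assert arand(seg, gt) == pytest.approx(arand(seg_p, gt), abs=1e-12)


class TestAp75:
    def test_perfect_match_is_one_everywhere(self, small_mito):
        _, lab = small_mito
        ap, counts = ap75(lab, lab)
        for name, value in ap.items():
            assert value == pytest.approx(1.0)
            assert counts[name]["fp"] == 0 and counts[name]["fn"] == 0

    def test_one_hit_one_miss_matches_enumeration(self):
        """2 gt cubes, one predicted perfectly: the PR curve has a single TP
        at precision 1 and recall 1/2, so AP = 0.5."""
        gt = np.zeros((2, 8, 8), dtype=int)
        gt[:, :3, :3] = 1
        gt[:, 5:, 5:] = 2
        pred = np.where(gt == 1, 4, 0)
        ap, counts = ap75(pred, gt)
        assert ap["all"] == pytest.approx(0.5)
        assert counts["all"] == {"tp": 1, "fp": 0, "fn": 1}

    def test_iou_half_pair_counts_fn_and_fp(self):
        """A pred overlapping its gt at IoU 0.5 (< 0.75) is one FN + one FP."""
        gt = np.zeros((1, 4, 4), dtype=int)
        gt[0, :2] = 1                      # 8 voxels
        pred = np.zeros_like(gt)
        pred[0, 1:3] = 9                   # 8 voxels, overlap 4 -> IoU 1/3 < .75
        ap, counts = ap75(pred, gt)
        assert counts["all"] == {"tp": 0, "fp": 1, "fn": 1}
        assert ap["all"] == pytest.approx(0.0)

    def test_monotone_in_iou_threshold(self, small_mito):
        _, lab = small_mito
        # a degraded prediction: erode every instance by one in-plane step
        from scipy import ndimage
        pred = np.zeros_like(lab.labels)
        for i in lab.ids():
            m = lab.labels == i
            for z in range(m.shape[0]):
                m[z] = ndimage.binary_erosion(m[z])
            pred[m] = i
        values = [ap75(pred, lab, iou_threshold=t)[0]["all"] for t in (0.5, 0.75, 0.9)]
        assert values[0] >= values[1] >= values[2]

    def test_empty_stratum_absent(self):
        gt = np.zeros((1, 6, 6), dtype=int)
        gt[0, :3, :3] = 1                  # 9 voxels: small only
        ap, _ = ap75(gt, gt)
        assert "small" in ap and "large" not in ap and "medium" not in ap
        assert ap["all"] == pytest.approx(1.0)


class TestEvaluateLabels:
    def test_bundles_all_metrics(self, small_mito):
        _, lab = small_mito
        rep = evaluate_labels(lab, lab)
        assert rep.voi_total == pytest.approx(0.0)
        assert rep.arand == pytest.approx(0.0)
        assert all(v == pytest.approx(1.0) for v in rep.ap75.values())
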