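"""Matching, PR curves, AP, F1-over-IoU, pixel kappa and bootstrap CIs.

The AP implementation is cross-checked against an independent brute-force
oracle that walks the 101-point recall grid and scans all curve points
per grid value (no vectorized envelope; deliberately naive).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wsldetect.evaluation import (
    COCO_THRESHOLDS,
    ap_at,
    average_precision,
    best_f1_cutoff,
    bootstrap_ci,
    counts_at_cutoff,
    evaluate_detections,
    f1_over_iou,
    map_range,
    match,
    pixel_kappa,
    pr_curve,
)
from wsldetect.geometry import BoundingBox, Detection

from conftest import box, det


def brute_force_ap(recall, precision) -> float:
    """Independent oracle: direct max-to-the-right scan per grid point."""
    if len(recall) == 0:
        return 0.0
    total = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for rr, pp in zip(recall, precision):
            if rr >= r and pp > best:
                best = pp
        total += best
    return total / 101


def random_instance(rng, n_images=3):
    """Small random detection problem (boxes on a 100x100 canvas)."""
    dets, gts = {}, {}
    for i in range(n_images):
        img = f"im{i}"
        gts[img] = []
        for _ in range(int(rng.integers(0, 5))):
            x0, y0 = rng.uniform(0, 80, 2)
            gts[img].append(BoundingBox(x0, y0, x0 + rng.uniform(5, 20),
                                        y0 + rng.uniform(5, 20)))
        dets[img] = []
        for g in gts[img]:
            if rng.random() < 0.8:  # jittered true detection
                dx, dy = rng.uniform(-4, 4, 2)
                dets[img].append(Detection(g.translate(dx, dy), "wsl",
                                           float(rng.uniform(0.1, 1))))
        for _ in range(int(rng.integers(0, 3))):  # spurious detections
            x0, y0 = rng.uniform(0, 80, 2)
            dets[img].append(Detection(
                BoundingBox(x0, y0, x0 + rng.uniform(5, 20),
                            y0 + rng.uniform(5, 20)),
                "wsl", float(rng.uniform(0.1, 1))))
    return dets, gts


class TestMatch:
    def test_perfect_single(self):
        g = box(0, 0, 10, 10)
        res = match([det(0, 0, 10, 10, 0.9)], [g], 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_greedy_one_to_one(self):
        g = box(0, 0, 10, 10)
        d1 = det(0, 0, 10, 9, 0.9)
        d2 = det(0, 0, 10, 11, 0.8)
        res = match([d1, d2], [g], 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)
        assert res.is_tp == [True, False]  # the higher-confidence one wins

    def test_no_detections_all_fn(self):
        res = match([], [box(0, 0, 5, 5)] * 3, 0.5)
        assert (res.tp, res.fp, res.fn) == (0, 0, 3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_conservation_at_every_threshold(self, seed):
        rng = np.random.default_rng(seed)
        dets, gts = random_instance(rng, n_images=1)
        for thr in (0.3, 0.5, 0.75):
            res = match(dets["im0"], gts["im0"], thr)
            assert res.tp + res.fn == len(gts["im0"])
            assert res.tp + res.fp == len(dets["im0"])
            matched = [a for a in res.assignment if a is not None]
            assert len(matched) == len(set(matched))  # one-to-one


class TestPRCurve:
    def test_perfect_detector_single_point(self):
        dets = {"a": [det(0, 0, 10, 10, 0.9)]}
        gts = {"a": [box(0, 0, 10, 10)]}
        r, p = pr_curve(dets, gts, 0.5)
        assert r[-1] == 1.0 and p[-1] == 1.0
        assert average_precision(r, p) == pytest.approx(1.0)

    def test_tp_fp_tp_ranking(self):
        # ranking TP(0.9), FP(0.8), TP(0.7) over 2 ground truths
        gts = {"a": [box(0, 0, 10, 10), box(50, 50, 60, 60)]}
        dets = {"a": [det(0, 0, 10, 10, 0.9),
                      det(80, 80, 90, 90, 0.8),
                      det(50, 50, 60, 60, 0.7)]}
        r, p = pr_curve(dets, gts, 0.5)
        assert list(r) == pytest.approx([0.5, 0.5, 1.0])
        assert list(p) == pytest.approx([1.0, 0.5, 2 / 3])

    def test_no_detections_empty_curve(self):
        r, p = pr_curve({"a": []}, {"a": [box(0, 0, 5, 5)]}, 0.5)
        assert len(r) == 0
        assert average_precision(r, p) == 0.0


class TestAveragePrecision:
    def test_tp_fp_tp_worked_value(self):
        # 51 grid points see precision 1, the remaining 50 see 2/3
        r = np.array([0.5, 0.5, 1.0])
        p = np.array([1.0, 0.5, 2 / 3])
        expected = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert average_precision(r, p) == pytest.approx(expected)
        assert brute_force_ap(r, p) == pytest.approx(expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets, gts = random_instance(rng)
        for thr in (0.5, 0.75):
            r, p = pr_curve(dets, gts, thr)
            assert average_precision(r, p) == pytest.approx(
                brute_force_ap(r, p), abs=1e-6)


class TestMapRange:
    def test_perfect_detector(self):
        dets = {"a": [det(0, 0, 10, 10, 0.9)]}
        gts = {"a": [box(0, 0, 10, 10)]}
        assert map_range(dets, gts) == pytest.approx(1.0)

    def test_iou_exactly_070_gives_half(self):
        # every detection has IoU exactly 0.7 with its gt: AP 1 for the
        # 5 thresholds 0.5-0.7, 0 for the rest -> mean 0.5
        gts = {"a": [box(0, 0, 10, 10)]}
        dets = {"a": [det(0, 0, 10, 7, 0.9)]}  # IoU = 70/100
        assert map_range(dets, gts) == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_never_exceeds_ap50(self, seed):
        rng = np.random.default_rng(seed)
        dets, gts = random_instance(rng)
        assert map_range(dets, gts) <= ap_at(dets, gts, 0.5) + 1e-12


class TestF1OverIoU:
    def test_perfect_detector_flat_one(self):
        dets = {"a": [det(0, 0, 10, 10, 0.9)]}
        gts = {"a": [box(0, 0, 10, 10)]}
        _, f1s = f1_over_iou(dets, gts)
        assert f1s == pytest.approx(np.ones_like(f1s))

    def test_half_precision_half_recall(self):
        # 1 TP + 1 FP and 1 TP + 1 FN: P = R = 0.5 -> F1 = 0.5
        gts = {"a": [box(0, 0, 10, 10), box(50, 50, 60, 60)]}
        dets = {"a": [det(0, 0, 10, 10, 0.9), det(80, 80, 90, 90, 0.8)]}
        tp, fp, fn = counts_at_cutoff(dets, gts, 0.5, 0.0)
        assert (tp, fp, fn) == (1, 1, 1)
        thr, f1s = f1_over_iou(dets, gts, cutoff=0.0)
        assert f1s[0] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_monotone_nonincreasing_in_iou(self, seed):
        rng = np.random.default_rng(seed)
        dets, gts = random_instance(rng)
        _, f1s = f1_over_iou(dets, gts, thresholds=np.linspace(0.3, 0.95, 14))
        assert all(a >= b - 1e-12 for a, b in zip(f1s, f1s[1:]))


class TestPixelKappa:
    DIMS = {"a": (10, 10)}

    def test_identical_sets_unity(self):
        boxes = {"a": [box(1, 1, 5, 5), box(6, 6, 9, 9)]}
        assert pixel_kappa(boxes, boxes, self.DIMS) == pytest.approx(1.0)

    def test_worked_100px_example(self):
        # 100-px image, gt mask 20 px, pred mask 20 px, overlap 10 px:
        # p_o = 0.8, p_e = 0.2*0.2 + 0.8*0.8 = 0.68, kappa = 0.12/0.32
        gt = {"a": [box(0, 0, 10, 2)]}          # rows 0-1: 20 px
        pred = {"a": [box(0, 1, 10, 3)]}        # rows 1-2: 20 px, overlap row 1
        assert pixel_kappa(pred, gt, self.DIMS) == pytest.approx(0.375)

    def test_constant_rater_scores_zero(self):
        pred = {"a": [box(0, 0, 10, 10)]}       # covers everything
        gt = {"a": [box(0, 0, 10, 2)]}
        assert pixel_kappa(pred, gt, self.DIMS) == pytest.approx(0.0)

    def test_both_constant_undefined(self):
        full = {"a": [box(0, 0, 10, 10)]}
        with pytest.raises(ZeroDivisionError):
            pixel_kappa(full, full, self.DIMS)

    def test_symmetric_and_translation_invariant(self):
        rng = np.random.default_rng(13)
        pred, gt = {}, {}
        dims = {}
        for i in range(3):
            img = f"im{i}"
            dims[img] = (60, 40)
            boxes = []
            for _ in range(2):
                x0, x1 = np.sort(rng.uniform(0, 50, 2))
                y0, y1 = np.sort(rng.uniform(0, 30, 2))
                boxes.append(box(x0, y0, x1 + 1, y1 + 1))
            pred[img] = boxes
            gt[img] = [box(5, 5, 25, 20)]
        v = pixel_kappa(pred, gt, dims)
        assert pixel_kappa(gt, pred, dims) == pytest.approx(v)
        shifted_pred = {k: [b.translate(3, 2) for b in v_] for k, v_ in pred.items()}
        shifted_gt = {k: [b.translate(3, 2) for b in v_] for k, v_ in gt.items()}
        dims_big = {k: (70, 50) for k in dims}
        v0 = pixel_kappa(pred, gt, dims_big)
        assert pixel_kappa(shifted_pred, shifted_gt, dims_big) == pytest.approx(v0)


class TestBootstrap:
    def test_constant_metric_degenerate_ci(self):
        lo, med, hi = bootstrap_ci(lambda ids: 0.7, ["a", "b", "c"],
                                   n_boot=50, seed=1)
        assert lo == med == hi == 0.7

    def test_fixed_seed_bit_identical(self):
        metric = lambda ids: float(len(set(ids)))
        a = bootstrap_ci(metric, [f"i{k}" for k in range(10)], n_boot=200, seed=3)
        b = bootstrap_ci(metric, [f"i{k}" for k in range(10)], n_boot=200, seed=3)
        assert a == b

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        values = {f"i{k}": float(rng.normal(0.5, 0.05)) for k in range(40)}
        metric = lambda ids: float(np.mean([values[i] for i in ids]))
        point = metric(sorted(values))
        lo, med, hi = bootstrap_ci(metric, sorted(values), n_boot=300, seed=5)
        assert lo <= point <= hi


class TestEvaluateDetections:
    def test_full_report_consistency(self):
        rng = np.random.default_rng(21)
        dets, gts = random_instance(rng, n_images=4)
        dims = {k: (100, 100) for k in gts}
        rep = evaluate_detections(dets, gts, dims)
        assert 0.0 <= rep.ap50 <= 1.0
        assert rep.map_50_95 <= rep.ap50 + 1e-12
        assert rep.tp + rep.fn == sum(len(v) for v in gts.values())
        if rep.tp + rep.fp:
            assert rep.precision == pytest.approx(rep.tp / (rep.tp + rep.fp))
        cutoff, f1 = best_f1_cutoff(dets, gts)
        assert rep.confidence_cutoff == cutoff
        assert rep.f1 == pytest.approx(f1)

    def test_bootstrap_cis_attached_and_ordered(self):
        rng = np.random.default_rng(22)
        dets, gts = random_instance(rng, n_images=5)
        dims = {k: (100, 100) for k in gts}
        rep = evaluate_detections(dets, gts, dims, n_boot=50, seed=9)
        for key in ("ap50", "map_50_95", "kappa"):
            lo, med, hi = rep.ci[key]
            assert lo <= med <= hi
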