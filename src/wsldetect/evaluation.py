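"""Detection accuracy metrics.

Matching, dataset-level precision–recall curves, COCO-style average
precision (101-point interpolation), F1-over-IoU curves, TP/FN/FP counts,
pixel-wise Cohen's kappa, and nonparametric bootstrap confidence
intervals.

A note on true negatives: for object detection there is no meaningful
"no detection overlapping background" event, so ROC curves and AUC are
not defined and are deliberately absent; precision–recall is the native
currency, and AP is its area by definition.

All dataset-level functions take detections and ground truths as mappings
``image_id -> list``; matching is always per image, pooling happens at
the curve level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .geometry import BoundingBox, Detection, iou

__all__ = [
    "MatchResult",
    "EvaluationReport",
    "match",
    "pr_curve",
    "average_precision",
    "ap_at",
    "map_range",
    "f1_over_iou",
    "counts_at_cutoff",
    "best_f1_cutoff",
    "pixel_kappa",
    "bootstrap_ci",
    "evaluate_detections",
    "COCO_THRESHOLDS",
]

COCO_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
_RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class MatchResult:
    """Outcome of greedy one-to-one matching at a single IoU threshold."""

    is_tp: list[bool]              # per detection, in the input order
    assignment: list[int | None]   # detection index -> matched gt index
    n_gt: int

    @property
    def tp(self) -> int:
        return sum(self.is_tp)

    @property
    def fp(self) -> int:
        return len(self.is_tp) - self.tp

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


def match(dets: Sequence[Detection], gts: Sequence[BoundingBox],
          iou_thr: float) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching.

    Detections are visited by descending confidence (ties: input order);
    each is matched to the unmatched ground truth with the highest IoU,
    provided that IoU is at least ``iou_thr``; otherwise it is a false
    positive.  Each ground truth absorbs at most one detection, so
    TP + FN equals the number of ground truths by construction.
    """
    is_tp = [False] * len(dets)
    assignment: list[int | None] = [None] * len(dets)
    taken = [False] * len(gts)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    for i in order:
        best_j, best_iou = None, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(dets[i].box, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None and best_iou >= iou_thr:
            taken[best_j] = True
            is_tp[i] = True
            assignment[i] = best_j
    return MatchResult(is_tp=is_tp, assignment=assignment, n_gt=len(gts))


def _pooled_flags(dets_by_img: Mapping[str, Sequence[Detection]],
                  gts_by_img: Mapping[str, Sequence[BoundingBox]],
                  iou_thr: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Match per image, then pool (confidence, tp-flag) pairs across the
    dataset sorted by descending confidence (ties: image id, then index,
    for determinism).  Returns (confidences, flags, n_gt_total)."""
    rows: list[tuple[float, str, int, bool]] = []
    n_gt = 0
    ids = set(dets_by_img) | set(gts_by_img)
    for img in sorted(ids):
        dets = list(dets_by_img.get(img, ()))
        gts = list(gts_by_img.get(img, ()))
        n_gt += len(gts)
        res = match(dets, gts, iou_thr)
        for k, d in enumerate(dets):
            rows.append((d.confidence, img, k, res.is_tp[k]))
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    conf = np.array([r[0] for r in rows], dtype=float)
    flags = np.array([r[3] for r in rows], dtype=bool)
    return conf, flags, n_gt


def pr_curve(dets_by_img: Mapping[str, Sequence[Detection]],
             gts_by_img: Mapping[str, Sequence[BoundingBox]],
             iou_thr: float) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (recall, precision) points as the confidence cutoff
    sweeps down the pooled dataset-level ranking.

    One point per ranked detection; empty when there are no detections.
    """
    _, flags, n_gt = _pooled_flags(dets_by_img, gts_by_img, iou_thr)
    if flags.size == 0:
        return np.empty(0), np.empty(0)
    cum_tp = np.cumsum(flags)
    ranks = np.arange(1, flags.size + 1)
    precision = cum_tp / ranks
    recall = cum_tp / n_gt if n_gt > 0 else np.zeros_like(precision)
    return recall, precision


def average_precision(recall: np.ndarray, precision: np.ndarray) -> float:
    """COCO 101-point interpolated average precision.

    Mean over the recall grid {0, 0.01, ..., 1} of the maximum precision
    attained at recall >= the grid point; 0 for an empty curve.
    """
    recall = np.asarray(recall, dtype=float)
    precision = np.asarray(precision, dtype=float)
    if recall.size == 0:
        return 0.0
    # envelope: max precision to the right, computed once
    order = np.argsort(recall, kind="stable")
    r = recall[order]
    p = precision[order]
    p_env = np.maximum.accumulate(p[::-1])[::-1]
    idx = np.searchsorted(r, _RECALL_GRID, side="left")
    vals = np.where(idx < r.size, p_env[np.minimum(idx, r.size - 1)], 0.0)
    return float(vals.mean())


def ap_at(dets_by_img, gts_by_img, iou_thr: float = 0.5) -> float:
    """AP at a single IoU threshold (AP@0.5 by default)."""
    return average_precision(*pr_curve(dets_by_img, gts_by_img, iou_thr))


def map_range(dets_by_img, gts_by_img,
              thresholds: Iterable[float] = COCO_THRESHOLDS) -> float:
    """Mean AP over an IoU-threshold range (COCO 0.50:0.05:0.95 default)."""
    thresholds = list(thresholds)
    return float(np.mean([ap_at(dets_by_img, gts_by_img, t) for t in thresholds]))


def counts_at_cutoff(dets_by_img, gts_by_img, iou_thr: float,
                     cutoff: float) -> tuple[int, int, int]:
    """(TP, FP, FN) keeping only detections with confidence >= cutoff."""
    tp = fp = fn = 0
    ids = set(dets_by_img) | set(gts_by_img)
    for img in sorted(ids):
        dets = [d for d in dets_by_img.get(img, ()) if d.confidence >= cutoff]
        gts = list(gts_by_img.get(img, ()))
        res = match(dets, gts, iou_thr)
        tp += res.tp
        fp += res.fp
        fn += res.fn
    return tp, fp, fn


def _f1(tp: int, fp: int, fn: int) -> float:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


def best_f1_cutoff(dets_by_img, gts_by_img, iou_thr: float = 0.5) -> tuple[float, float]:
    """Confidence cutoff maximizing dataset-level F1 at ``iou_thr``.

    Candidates are the distinct detection confidences (sweeping the pooled
    ranking); returns (cutoff, best F1).  With no detections the cutoff is
    0 and F1 is 0.
    """
    conf, flags, n_gt = _pooled_flags(dets_by_img, gts_by_img, iou_thr)
    if conf.size == 0:
        return 0.0, 0.0
    cum_tp = np.cumsum(flags)
    ranks = np.arange(1, flags.size + 1)
    precision = cum_tp / ranks
    recall = cum_tp / n_gt if n_gt else np.zeros_like(precision)
    f1 = np.where(precision + recall > 0,
                  2 * precision * recall / np.maximum(precision + recall, 1e-300), 0.0)
    # only cut at the last detection of each distinct confidence value
    is_last = np.ones(conf.size, dtype=bool)
    is_last[:-1] = conf[:-1] != conf[1:]
    cand = np.flatnonzero(is_last)
    best = cand[np.argmax(f1[cand])]
    return float(conf[best]), float(f1[best])


def f1_over_iou(dets_by_img, gts_by_img,
                thresholds: Iterable[float] = COCO_THRESHOLDS,
                cutoff: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """F1 score as a function of the IoU matching threshold.

    The operating confidence cutoff is fixed across the curve; by default
    it is the one maximizing F1 at IoU 0.5, so the curve shows pure
    localisation degradation.  Monotone non-increasing in the threshold:
    raising the IoU bar can only shrink the match set.
    """
    if cutoff is None:
        cutoff, _ = best_f1_cutoff(dets_by_img, gts_by_img, 0.5)
    thr = np.array(sorted(thresholds), dtype=float)
    f1s = np.empty_like(thr)
    for i, t in enumerate(thr):
        tp, fp, fn = counts_at_cutoff(dets_by_img, gts_by_img, float(t), cutoff)
        f1s[i] = _f1(tp, fp, fn)
    return thr, f1s


# ---------------------------------------------------------------------------
# pixel-wise Cohen's kappa


def _rasterize(boxes: Iterable[BoundingBox], width: int, height: int) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    for b in boxes:
        x0 = max(int(np.floor(b.x_min + 0.5)), 0)
        y0 = max(int(np.floor(b.y_min + 0.5)), 0)
        x1 = min(int(np.floor(b.x_max + 0.5)), width)
        y1 = min(int(np.floor(b.y_max + 0.5)), height)
        if x1 > x0 and y1 > y0:
            mask[y0:y1, x0:x1] = True
    return mask


def _confusion(pred: Iterable[BoundingBox], gt: Iterable[BoundingBox],
               width: int, height: int) -> np.ndarray:
    p = _rasterize(pred, width, height)
    g = _rasterize(gt, width, height)
    both = int(np.count_nonzero(p & g))
    p_only = int(np.count_nonzero(p)) - both
    g_only = int(np.count_nonzero(g)) - both
    neither = width * height - both - p_only - g_only
    return np.array([[both, p_only], [g_only, neither]], dtype=np.int64)


def _kappa_from_confusion(c: np.ndarray) -> float:
    n = c.sum()
    p_o = (c[0, 0] + c[1, 1]) / n
    pred_pos = (c[0, 0] + c[0, 1]) / n
    gt_pos = (c[0, 0] + c[1, 0]) / n
    p_e = pred_pos * gt_pos + (1 - pred_pos) * (1 - gt_pos)
    if 1.0 - p_e == 0.0:
        raise ZeroDivisionError(
            "pixel kappa undefined: both raters are constant (chance agreement 1)")
    return float((p_o - p_e) / (1.0 - p_e))


def pixel_kappa(pred_by_img: Mapping[str, Sequence[BoundingBox]],
                gt_by_img: Mapping[str, Sequence[BoundingBox]],
                dims_by_img: Mapping[str, tuple[int, int]],
                pooled: bool = True) -> float:
    """Chance-corrected pixel agreement between two box sets.

    Each set is rasterized per image as the union of filled rectangles
    into a binary mask (original-frame resolution), and the 2x2 pixel
    confusion matrix is accumulated.  By default matrices are summed over
    the whole dataset before computing kappa (a single dataset-level
    value, stable when individual images have no lesions);
    ``pooled=False`` averages per-image kappas instead, skipping images
    where kappa is undefined.

    Raises ``ZeroDivisionError`` when chance agreement is 1 (both raters
    constant over every pixel considered).
    """
    ids = sorted(set(pred_by_img) | set(gt_by_img))
    if not ids:
        raise ValueError("no images to evaluate")
    if pooled:
        total = np.zeros((2, 2), dtype=np.int64)
        for img in ids:
            w, h = dims_by_img[img]
            total += _confusion(pred_by_img.get(img, ()), gt_by_img.get(img, ()), w, h)
        return _kappa_from_confusion(total)
    vals = []
    for img in ids:
        w, h = dims_by_img[img]
        c = _confusion(pred_by_img.get(img, ()), gt_by_img.get(img, ()), w, h)
        try:
            vals.append(_kappa_from_confusion(c))
        except ZeroDivisionError:
            continue
    if not vals:
        raise ZeroDivisionError("pixel kappa undefined on every image")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(metric: Callable[[Sequence[str]], float],
                 image_ids: Sequence[str], n_boot: int = 1000,
                 seed: int = 0, alpha: float = 0.05,
                 ) -> tuple[float, float, float]:
    """Percentile bootstrap over images.

    ``metric`` maps a list of image ids (with repeats) to a scalar; images
    are resampled with replacement ``n_boot`` times and the
    ``alpha/2``/median/``1-alpha/2`` percentiles of the replicate
    distribution are returned as ``(lo, median, hi)``.  Fully determined
    by ``seed``.
    """
    if not image_ids:
        raise ValueError("need at least one image")
    rng = np.random.default_rng(seed)
    ids = list(image_ids)
    reps = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        sample = [ids[i] for i in rng.integers(0, len(ids), size=len(ids))]
        reps[b] = metric(sample)
    lo, med, hi = np.percentile(reps, [100 * alpha / 2, 50, 100 * (1 - alpha / 2)])
    return float(lo), float(med), float(hi)


# ---------------------------------------------------------------------------
# full report


@dataclass
class EvaluationReport:
    """Dataset-level accuracy summary (one detection arm, one class)."""

    kappa: float
    ap50: float
    map_50_95: float
    f1: float
    confidence_cutoff: float
    tp: int
    fn: int
    fp: int
    precision: float
    recall: float
    f1_curve_thresholds: list[float] = field(default_factory=list)
    f1_curve_values: list[float] = field(default_factory=list)
    ci: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "ap50": self.ap50,
            "map_50_95": self.map_50_95,
            "f1": self.f1,
            "confidence_cutoff": self.confidence_cutoff,
            "tp": self.tp, "fn": self.fn, "fp": self.fp,
            "precision": self.precision, "recall": self.recall,
            "f1_curve": {"iou_thresholds": self.f1_curve_thresholds,
                         "f1": self.f1_curve_values},
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def evaluate_detections(dets_by_img: Mapping[str, Sequence[Detection]],
                        gts_by_img: Mapping[str, Sequence[BoundingBox]],
                        dims_by_img: Mapping[str, tuple[int, int]],
                        n_boot: int = 0, seed: int = 0,
                        kappa_pooled: bool = True) -> EvaluationReport:
    """Compute the full accuracy report for one detection arm.

    TP/FN/FP and F1 are reported at the confidence cutoff that maximizes
    F1 at IoU 0.5 (the cutoff is included in the report).  With
    ``n_boot > 0``, percentile-bootstrap CIs over images are attached for
    kappa, AP@0.5 and mAP@0.5:0.95.
    """
    cutoff, f1_best = best_f1_cutoff(dets_by_img, gts_by_img, 0.5)
    tp, fp, fn = counts_at_cutoff(dets_by_img, gts_by_img, 0.5, cutoff)
    thr, f1s = f1_over_iou(dets_by_img, gts_by_img, cutoff=cutoff)
    try:
        kappa = pixel_kappa(
            {i: [d.box for d in dets_by_img.get(i, ())] for i in dims_by_img},
            gts_by_img, dims_by_img, pooled=kappa_pooled)
    except ZeroDivisionError:
        kappa = float("nan")
    report = EvaluationReport(
        kappa=kappa,
        ap50=ap_at(dets_by_img, gts_by_img, 0.5),
        map_50_95=map_range(dets_by_img, gts_by_img),
        f1=f1_best,
        confidence_cutoff=cutoff,
        tp=tp, fn=fn, fp=fp,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn) if tp + fn else 0.0,
        f1_curve_thresholds=[float(t) for t in thr],
        f1_curve_values=[float(v) for v in f1s],
    )
    if n_boot > 0:
        ids = sorted(dims_by_img)

        def _sub(sample, fn_metric):
            # unique-name repeats so resampled duplicates count separately
            d = {f"{img}#{k}": dets_by_img.get(img, ()) for k, img in enumerate(sample)}
            g = {f"{img}#{k}": gts_by_img.get(img, ()) for k, img in enumerate(sample)}
            dims = {f"{img}#{k}": dims_by_img[img] for k, img in enumerate(sample)}
            return fn_metric(d, g, dims)

        report.ci = {
            "ap50": bootstrap_ci(
                lambda s: _sub(s, lambda d, g, m: ap_at(d, g, 0.5)),
                ids, n_boot=n_boot, seed=seed),
            "map_50_95": bootstrap_ci(
                lambda s: _sub(s, lambda d, g, m: map_range(d, g)),
                ids, n_boot=n_boot, seed=seed + 1),
            "kappa": bootstrap_ci(
                lambda s: _sub(s, lambda d, g, m: pixel_kappa(
                    {i: [x.box for x in d.get(i, ())] for i in m}, g, m,
                    pooled=kappa_pooled)),
                ids, n_boot=n_boot, seed=seed + 2),
        }
    return report
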