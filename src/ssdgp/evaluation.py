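"""Detection evaluation: IoU matching, precision/recall/F1, P-R curves,
VOC-style average precision, size-stratified recall, and an exact
McNemar paired comparison.

Conventions:

* A detection is a true positive when it can be greedily matched (in
  descending confidence, one detection per ground truth) to an unmatched
  ground-truth box of its class with IoU >= 0.5. Duplicate detections of
  an already-matched truth count as false positives; unmatched truths
  are false negatives.
* Precision, recall and F1 are reported as percentages:
  P = 100*TP/(TP+FP), R = 100*TP/(TP+FN), F1 = 2PR/(P+R).
* Average precision is the 11-point interpolated VOC-2007 form.
* Size strata (small <= 32x32 px, medium <= 96x96, large above) are
  computed on ground-truth areas in the *original* frame (560x475 for
  gastroscopy exports), not the resized network input.
* Two models are compared per ground-truth polyp with an exact
  two-sided McNemar test: with discordant counts b and c,
  p = min(1, 2*P[X <= min(b,c)]), X ~ Binomial(b+c, 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .multibox import Detection, PAPER_CONF_THRESHOLDS
from .preprocess import Box

__all__ = [
    "ConfusionCounts", "PRPoint", "PairedOutcomes", "GroundTruth",
    "iou", "match_detections", "precision", "recall", "f1",
    "pr_curve", "average_precision", "map_over_classes",
    "stratified_recall", "mcnemar_exact", "paired_outcomes",
    "evaluation_report", "SIZE_BOUNDS",
]

# stratum area bounds in original-frame pixels: 32*32 and 96*96
SIZE_BOUNDS = (32 * 32, 96 * 96)


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    box: Box
    class_id: int = 1


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float  # percent
    recall: float     # percent


@dataclass(frozen=True)
class PairedOutcomes:
    """2x2 per-polyp correctness table of two models.

    both: both correct; a_only: A correct & B wrong; b_only: B correct &
    A wrong; neither: both wrong.
    """

    both: int
    a_only: int
    b_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes in the same frame."""
    if a.frame != b.frame:
        raise ValueError(f"boxes live in different frames: {a.frame} vs {b.frame}")
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def match_detections(dets: list[Detection], truths: list[GroundTruth],
                     iou_threshold: float = 0.5, conf_threshold: float = 0.5,
                     ) -> tuple[ConfusionCounts, np.ndarray]:
    """Greedy confidence-ordered matching over a whole evaluation set.

    Detections below ``conf_threshold`` are discarded; the rest are
    processed in descending confidence, each matched to the unmatched
    same-image same-class truth of highest IoU >= ``iou_threshold``.
    Returns the counts and a per-truth detected/missed flag array
    aligned with ``truths`` (the input to the paired McNemar table).
    """
    detected = np.zeros(len(truths), dtype=bool)
    by_image: dict[tuple[str, int], list[int]] = {}
    for i, t in enumerate(truths):
        by_image.setdefault((t.image_id, t.class_id), []).append(i)
    kept = sorted((d for d in dets if d.confidence >= conf_threshold),
                  key=lambda d: -d.confidence)
    fp = 0
    for d in kept:
        candidates = [i for i in by_image.get((d.image_id, d.class_id), []) if not detected[i]]
        best, best_iou = -1, -1.0
        for i in candidates:  # first-listed truth wins exact IoU ties
            v = iou(d.box, truths[i].box)
            if v >= iou_threshold and v > best_iou:
                best, best_iou = i, v
        if best >= 0:
            detected[best] = True
        else:
            fp += 1
    tp = int(detected.sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=len(truths) - tp), detected


def _pct(num: float, den: float, what: str) -> float:
    if den <= 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting 0")
        return 0.0
    return 100.0 * num / den


def precision(c: ConfusionCounts) -> float:
    return _pct(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _pct(c.tp, c.tp + c.fn, "recall")


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if p + r == 0:
        warnings.warn("F1 undefined (precision + recall = 0); reporting 0")
        return 0.0
    return 2 * p * r / (p + r)


def pr_curve(dets: list[Detection], truths: list[GroundTruth],
             thresholds=PAPER_CONF_THRESHOLDS, iou_threshold: float = 0.5,
             ) -> list[PRPoint]:
    """Precision/recall at each confidence threshold of the 19-point grid."""
    pts = []
    for thr in thresholds:
        c, _ = match_detections(dets, truths, iou_threshold, thr)
        pts.append(PRPoint(float(thr), precision(c), recall(c)))
    return pts


def _class_ap(dets: list[Detection], truths: list[GroundTruth],
              iou_threshold: float) -> float:
    """11-point interpolated AP (percent) for a single class."""
    n_truth = len(truths)
    order = sorted(dets, key=lambda d: -d.confidence)
    detected = np.zeros(n_truth, dtype=bool)
    by_image: dict[str, list[int]] = {}
    for i, t in enumerate(truths):
        by_image.setdefault(t.image_id, []).append(i)
    tp_flags = np.zeros(len(order), dtype=bool)
    for k, d in enumerate(order):
        best, best_iou = -1, -1.0
        for i in by_image.get(d.image_id, []):
            if detected[i]:
                continue
            v = iou(d.box, truths[i].box)
            if v >= iou_threshold and v > best_iou:
                best, best_iou = i, v
        if best >= 0:
            detected[best] = True
            tp_flags[k] = True
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    rec = tp_cum / n_truth
    prec = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    ap = 0.0
    for r in np.linspace(0, 1, 11):
        mask = rec >= r
        ap += prec[mask].max() if mask.any() else 0.0
    return 100.0 * ap / 11


def average_precision(dets: list[Detection], truths: list[GroundTruth],
                      iou_threshold: float = 0.5) -> float:
    """VOC-2007 11-point interpolated average precision, in percent."""
    if not truths:
        warnings.warn("no ground truth; AP undefined, reporting 0")
        return 0.0
    return _class_ap(dets, truths, iou_threshold)


def map_over_classes(dets: list[Detection], truths: list[GroundTruth],
                     iou_threshold: float = 0.5) -> float:
    """Mean AP over the classes that have ground truth."""
    classes = sorted({t.class_id for t in truths})
    det_classes = {d.class_id for d in dets}
    for c in sorted(det_classes - set(classes)):
        warnings.warn(f"class {c} has detections but no ground truth; excluded from mAP")
    aps = []
    for c in classes:
        aps.append(_class_ap([d for d in dets if d.class_id == c],
                             [t for t in truths if t.class_id == c], iou_threshold))
    if not aps:
        warnings.warn("no classes with ground truth; mAP undefined, reporting 0")
        return 0.0
    return float(np.mean(aps))


def stratified_recall(dets: list[Detection], truths: list[GroundTruth],
                      iou_threshold: float = 0.5, conf_threshold: float = 0.5,
                      bounds=SIZE_BOUNDS) -> dict[str, tuple[int, int, float | None]]:
    """Recall by ground-truth size stratum.

    Areas are taken from the truth boxes' own frame, which must be the
    original acquisition frame for the strata to mean what they should.
    Returns ``{stratum: (detected, total, recall-or-None)}``; an empty
    stratum reports ``None``.
    """
    lo, hi = bounds
    _, flags = match_detections(dets, truths, iou_threshold, conf_threshold)
    strata = {"small": [0, 0], "medium": [0, 0], "large": [0, 0]}
    for t, ok in zip(truths, flags):
        a = t.box.area
        name = "small" if a <= lo else ("medium" if a <= hi else "large")
        strata[name][1] += 1
        strata[name][0] += int(ok)
    return {k: (d, n, (d / n) if n else None) for k, (d, n) in strata.items()}


def paired_outcomes(flags_a: np.ndarray, flags_b: np.ndarray) -> PairedOutcomes:
    """Per-truth correctness flags of two models -> the 2x2 table."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag arrays must align on the same ground truths")
    return PairedOutcomes(both=int((a & b).sum()), a_only=int((a & ~b).sum()),
                          b_only=int((~a & b).sum()), neither=int((~a & ~b).sum()))


def mcnemar_exact(outcomes: PairedOutcomes | tuple[int, int]) -> float:
    """Two-sided exact McNemar p-value from the discordant counts.

    Uses the binomial form: with b and c the discordant counts,
    p = min(1, 2*P[X <= min(b, c)]) for X ~ Binomial(b+c, 1/2); if
    b = c = 0 the models are indistinguishable and p = 1.
    """
    if isinstance(outcomes, PairedOutcomes):
        b, c = outcomes.a_only, outcomes.b_only
    else:
        b, c = outcomes
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


def evaluation_report(dets: list[Detection], truths: list[GroundTruth],
                      iou_threshold: float = 0.5, conf_threshold: float = 0.5,
                      thresholds=PAPER_CONF_THRESHOLDS) -> dict:
    """The full protocol as a JSON-ready dict: counts, the three basic
    metrics, AP, size strata and the P-R grid."""
    counts, flags = match_detections(dets, truths, iou_threshold, conf_threshold)
    strata = stratified_recall(dets, truths, iou_threshold, conf_threshold)
    return {
        "iou_threshold": iou_threshold,
        "conf_threshold": conf_threshold,
        "counts": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn},
        "precision_pct": precision(counts),
        "recall_pct": recall(counts),
        "f1_pct": f1(counts),
        "average_precision_pct": average_precision(dets, truths, iou_threshold),
        "strata": {k: {"detected": d, "total": n,
                       "recall": (round(r, 4) if r is not None else None)}
                   for k, (d, n, r) in strata.items()},
        "pr_curve": [{"threshold": p.threshold, "precision_pct": p.precision,
                      "recall_pct": p.recall} for p in
                     pr_curve(dets, truths, thresholds, iou_threshold)],
        "per_truth_detected": [bool(x) for x in flags],
    }
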