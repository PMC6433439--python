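"""Metric protocol: IoU, greedy matching vs an exhaustive oracle,
percentage metrics against published-count fixtures, AP, strata, and
the exact McNemar test."""

import numpy as np
import pytest

from ssdgp.evaluation import (ConfusionCounts, GroundTruth, PairedOutcomes,
                              average_precision, f1, iou, map_over_classes,
                              match_detections, mcnemar_exact, paired_outcomes,
                              pr_curve, precision, recall, stratified_recall)
from ssdgp.multibox import Detection
from ssdgp.preprocess import Box

FRAME = (560, 475)


def B(x1, y1, x2, y2):
    return Box(x1, y1, x2, y2, frame=FRAME)


def D(img, conf, box, cls=1):
    return Detection(img, cls, conf, box)


def T(img, box, cls=1):
    return GroundTruth(img, box, cls)


# ---------------------------------------------------------------- iou


def test_iou_examples():
    assert iou(B(0, 0, 10, 10), B(0, 0, 10, 10)) == 1.0
    assert iou(B(0, 0, 10, 10), B(20, 20, 30, 30)) == 0.0
    assert iou(B(0, 0, 10, 10), B(5, 5, 15, 15)) == pytest.approx(25 / 175)


def test_iou_requires_same_frame():
    with pytest.raises(ValueError):
        iou(B(0, 0, 10, 10), Box(0, 0, 10, 10, frame=(300, 300)))


# ---------------------------------------------------------------- matching


def test_perfect_detections_no_errors():
    truths = [T("a", B(10, 10, 50, 50)), T("a", B(100, 100, 200, 220)), T("b", B(5, 5, 30, 30))]
    dets = [D(t.image_id, 1.0, t.box) for t in truths]
    c, flags = match_detections(dets, truths)
    assert (c.tp, c.fp, c.fn) == (3, 0, 0)
    assert flags.all()


def test_duplicate_detection_counts_as_fp():
    truths = [T("a", B(10, 10, 50, 50))]
    dets = [D("a", 0.9, B(10, 10, 50, 50)), D("a", 0.8, B(11, 11, 50, 50))]
    c, _ = match_detections(dets, truths)
    assert (c.tp, c.fp, c.fn) == (1, 1, 0)


def test_conf_threshold_discards_before_matching():
    truths = [T("a", B(10, 10, 50, 50))]
    dets = [D("a", 0.4, B(10, 10, 50, 50))]
    c, _ = match_detections(dets, truths, conf_threshold=0.5)
    assert (c.tp, c.fp, c.fn) == (0, 0, 1)


def test_iou_exactly_half_is_positive():
    truths = [T("a", B(0, 0, 10, 10))]
    dets = [D("a", 0.9, B(0, 0, 10, 5))]  # IoU exactly 0.5
    c, _ = match_detections(dets, truths)
    assert c.tp == 1


def oracle_greedy(dets, truths, iou_thr, conf_thr):
    """Replay the greedy rule from a dense IoU matrix, pure python."""
    kept = sorted([d for d in dets if d.confidence >= conf_thr], key=lambda d: -d.confidence)
    matched = [False] * len(truths)
    tp = fp = 0
    for d in kept:
        best, best_v = -1, -1.0
        for i, t in enumerate(truths):
            if matched[i] or t.image_id != d.image_id or t.class_id != d.class_id:
                continue
            v = iou(d.box, t.box)
            if v >= iou_thr and v > best_v:
                best, best_v = i, v
        if best >= 0:
            matched[best] = True
            tp += 1
        else:
            fp += 1
    return tp, fp, len(truths) - tp, matched


@pytest.mark.parametrize("trial", range(25))
def test_greedy_matcher_equals_oracle_on_random_scenarios(trial):
    rng = np.random.default_rng(1000 + trial)
    truths, dets = [], []
    for img in range(3):
        for _ in range(rng.integers(0, 4)):
            x, y = rng.uniform(0, 400, 2)
            w, h = rng.uniform(20, 120, 2)
            truths.append(T(f"i{img}", B(x, y, min(x + w, 560), min(y + h, 475))))
        for _ in range(rng.integers(0, 6)):
            x, y = rng.uniform(0, 400, 2)
            w, h = rng.uniform(20, 120, 2)
            dets.append(D(f"i{img}", float(rng.random()),
                          B(x, y, min(x + w, 560), min(y + h, 475))))
    c, flags = match_detections(dets, truths, 0.5, 0.3)
    tp, fp, fn, matched = oracle_greedy(dets, truths, 0.5, 0.3)
    assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
    assert list(flags) == matched


def test_matching_permutation_invariant_in_truth_order():
    rng = np.random.default_rng(5)
    truths = [T("a", B(x, y, x + w, y + h)) for x, y, w, h in
              rng.uniform(10, 100, size=(6, 4))]
    dets = [D("a", float(rng.random()), B(x, y, x + w, y + h)) for x, y, w, h in
            rng.uniform(10, 100, size=(8, 4))]
    c1, f1_ = match_detections(dets, truths, 0.5, 0.0)
    perm = rng.permutation(len(truths))
    c2, f2 = match_detections(dets, [truths[i] for i in perm], 0.5, 0.0)
    assert (c1.tp, c1.fp, c1.fn) == (c2.tp, c2.fp, c2.fn)
    assert list(f1_) == list(np.array(f2)[np.argsort(perm)])


# ---------------------------------------------------------------- metrics


@pytest.mark.parametrize("counts,expect", [
    ((139, 9, 43), (93.92, 76.37, 84.24)),
    ((121, 7, 61), (94.53, 66.48, 78.06)),
])
def test_metrics_reproduce_published_counts(counts, expect):
    c = ConfusionCounts(*counts)
    assert round(precision(c), 2) == expect[0]
    assert round(recall(c), 2) == expect[1]
    assert round(f1(c), 2) == expect[2]


def test_zero_counts_yield_zero_with_warning():
    c = ConfusionCounts(0, 5, 5)
    assert precision(c) == 0.0 and recall(c) == 0.0
    with pytest.warns(UserWarning):  # P + R = 0 leaves F1 undefined
        assert f1(c) == 0.0
    with pytest.warns(UserWarning):  # TP + FP = 0 leaves precision undefined
        assert precision(ConfusionCounts(0, 0, 5)) == 0.0


def test_f1_harmonic_identity():
    rng = np.random.default_rng(0)
    for _ in range(50):
        tp, fp, fn = rng.integers(1, 200, 3)
        c = ConfusionCounts(int(tp), int(fp), int(fn))
        assert f1(c) == pytest.approx(200 * tp / (2 * tp + fp + fn), abs=1e-9)


# ---------------------------------------------------------------- curves / AP


def test_pr_curve_perfect_detector_and_monotone_recall():
    truths = [T("a", B(10, 10, 50, 50)), T("b", B(10, 10, 80, 90))]
    dets = [D(t.image_id, 0.99, t.box) for t in truths]
    pts = pr_curve(dets, truths)
    assert len(pts) == 19
    assert all(p.precision == 100.0 and p.recall == 100.0 for p in pts)

    rng = np.random.default_rng(2)
    dets = [D("a", float(rng.random()), B(x, y, x + w, y + h)) for x, y, w, h in
            rng.uniform(5, 100, size=(30, 4))]
    rec = [p.recall for p in pr_curve(dets, truths)]
    assert all(a >= b for a, b in zip(rec, rec[1:]))


def test_average_precision_limits():
    truths = [T("a", B(10, 10, 50, 50)), T("a", B(100, 100, 200, 200))]
    perfect = [D("a", 0.9, t.box) for t in truths]
    assert average_precision(perfect, truths) == 100.0
    wrong = [D("a", 0.9, B(300, 300, 400, 400)), D("a", 0.8, B(250, 250, 280, 280))]
    assert average_precision(wrong, truths) == 0.0


def brute_force_ap11(prec_rec: list[tuple[float, float]]) -> float:
    total = 0.0
    for r in [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]:
        cands = [p for p, rr in prec_rec if rr >= r]
        total += max(cands) if cands else 0.0
    return 100 * total / 11


def test_average_precision_matches_11_point_brute_force():
    rng = np.random.default_rng(9)
    truths = [T("a", B(x, y, x + w, y + h)) for x, y, w, h in
              np.column_stack([rng.uniform(10, 300, (5, 2)), rng.uniform(30, 100, (5, 2))])]
    dets = []
    for t in truths[:4]:
        j = rng.uniform(-6, 6, 4)
        dets.append(D("a", float(rng.random()),
                      B(t.box.xmin + j[0], t.box.ymin + j[1],
                        t.box.xmax + j[2], t.box.ymax + j[3])))
    dets += [D("a", float(rng.random()), B(400, 400, 450, 440)) for _ in range(3)]
    # independent rank-by-rank P-R pairs
    order = sorted(dets, key=lambda d: -d.confidence)
    pr = []
    for k in range(1, len(order) + 1):
        tp, fp, fn, _ = oracle_greedy(order[:k], truths, 0.5, 0.0)
        pr.append((tp / max(tp + fp, 1), tp / len(truths)))
    assert average_precision(dets, truths) == pytest.approx(brute_force_ap11(pr))


def test_map_ground_truth_as_detections_is_100():
    rng = np.random.default_rng(4)
    truths = []
    for img in range(4):
        for _ in range(rng.integers(1, 4)):
            x, y = rng.uniform(0, 300, 2)
            w, h = rng.uniform(20, 100, 2)
            truths.append(T(f"i{img}", B(x, y, min(x + w, 560), min(y + h, 475))))
    dets = [D(t.image_id, 1.0, t.box) for t in truths]
    assert map_over_classes(dets, truths) == 100.0


# ---------------------------------------------------------------- strata


def test_stratified_recall_reproduces_published_fractions():
    # 99 small / 76 medium / 7 large polyps; detect 66, 61, 6 of them
    truths, dets = [], []
    k = 0
    for n, hit, edge in [(99, 66, 30), (76, 61, 60), (7, 6, 120)]:
        for i in range(n):
            b = B(5, 5, 5 + edge, 5 + edge)
            truths.append(T(f"img{k}", b))
            if i < hit:
                dets.append(D(f"img{k}", 0.9, b))
            k += 1
    out = stratified_recall(dets, truths)
    assert out["small"][:2] == (66, 99)
    assert out["medium"][:2] == (61, 76)
    assert out["large"][:2] == (6, 7)
    assert round(out["small"][2], 4) == 0.6667
    assert round(out["medium"][2], 4) == 0.8026
    assert round(out["large"][2], 4) == 0.8571


def test_stratified_recall_boundaries_and_empty_stratum():
    truths = [T("a", B(0, 0, 32, 32)),   # area 1024 -> small
              T("a", B(100, 100, 196, 196))]  # area 9216 -> medium
    dets = [D("a", 0.9, t.box) for t in truths]
    out = stratified_recall(dets, truths)
    assert out["small"][:2] == (1, 1)
    assert out["medium"][:2] == (1, 1)
    assert out["large"] == (0, 0, None)


# ---------------------------------------------------------------- McNemar


def test_mcnemar_reproduces_published_p_value():
    # discordant counts from the paired 182-polyp table: 22 vs 4
    assert mcnemar_exact((22, 4)) == pytest.approx(0.00053, abs=5e-6)


def test_mcnemar_agrees_with_statsmodels_exact():
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    for b, c in [(22, 4), (3, 1), (10, 10), (0, 7), (1, 0)]:
        table = [[50, b], [c, 30]]
        want = float(sm.mcnemar(table, exact=True).pvalue)
        assert mcnemar_exact((b, c)) == pytest.approx(want, rel=1e-10)


def test_mcnemar_small_example_and_edge_cases():
    assert mcnemar_exact((3, 1)) == pytest.approx(0.625)  # 2*sum_{k<=1} C(4,k)/16
    assert mcnemar_exact((0, 0)) == 1.0
    assert mcnemar_exact((5, 5)) == 1.0
    with pytest.raises(ValueError):
        mcnemar_exact((-1, 2))


def test_mcnemar_symmetry_and_range():
    rng = np.random.default_rng(8)
    for _ in range(50):
        b, c = map(int, rng.integers(0, 40, 2))
        p = mcnemar_exact((b, c))
        assert p == mcnemar_exact((c, b))
        assert 0 < p <= 1


def test_paired_outcomes_from_flags():
    a = np.array([True, True, False, False, True])
    b = np.array([True, False, True, False, True])
    t = paired_outcomes(a, b)
    assert (t.both, t.a_only, t.b_only, t.neither) == (2, 1, 1, 1)
    assert t.total == 5
    # the published paired table: 117 both, 4 baseline-only, 22 proposed-only, 39 neither
    table = PairedOutcomes(both=117, a_only=4, b_only=22, neither=39)
    assert table.total == 182
    assert mcnemar_exact(table) == pytest.approx(0.00053, abs=5e-6)
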