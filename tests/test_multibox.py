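"""Prior generation, prior-truth matching, the multibox loss (against an
independent reimplementation), box coding and NMS."""

import numpy as np
import pytest

from ssdgp import nn
from ssdgp.multibox import (TrainConfig, decode_and_nms, decode_boxes,
                            encode_boxes, generate_priors, iou_matrix,
                            match_priors, multibox_loss, nms)
from ssdgp.netbuilder import default_plan


@pytest.fixture(scope="module")
def desk_priors(desk_plan):
    return generate_priors(desk_plan)


# ---------------------------------------------------------------- priors


def test_prior_count_closed_form(desk_plan):
    priors = generate_priors(desk_plan)
    expect = sum(lv.spatial ** 2 * lv.boxes_per_cell for lv in desk_plan.levels)
    assert len(priors) == expect


def test_full_plan_prior_count_is_canonical():
    # 38^2*4 + 19^2*6 + 10^2*6 + 5^2*6 + 3^2*4 + 1*4
    plan = default_plan("ssd", 300, 1.0)
    assert len(generate_priors(plan)) == 8732


def test_single_cell_level_priors_centered(desk_plan):
    priors = generate_priors(desk_plan)
    last = desk_plan.levels[-1]
    tail = priors[-last.boxes_per_cell:]
    centers = (tail[:, :2] + tail[:, 2:]) / 2
    np.testing.assert_allclose(centers, 0.5, atol=1e-9)


def test_priors_clipped_to_unit_square(desk_plan):
    priors = generate_priors(desk_plan)
    assert (priors >= 0).all() and (priors <= 1).all()
    assert (priors[:, 2] > priors[:, 0]).all() and (priors[:, 3] > priors[:, 1]).all()


def test_priors_deterministic(desk_plan):
    np.testing.assert_array_equal(generate_priors(desk_plan), generate_priors(desk_plan))


# ---------------------------------------------------------------- matching


def test_truth_identical_to_prior_matches_it(desk_priors):
    truth = desk_priors[[100]]
    loc_t, conf_t = match_priors(desk_priors, truth, np.array([1]))
    assert conf_t[100] == 1
    np.testing.assert_allclose(loc_t[100], 0.0, atol=1e-9)


def test_low_overlap_truth_still_gets_best_prior(desk_priors):
    truth = np.array([[0.001, 0.001, 0.012, 0.035]])  # tiny sliver box
    ious = iou_matrix(truth, desk_priors)[0]
    assert ious.max() < 0.5
    _, conf_t = match_priors(desk_priors, truth, np.array([1]))
    assert conf_t.sum() == 1
    assert conf_t[ious.argmax()] == 1


def test_no_truths_all_background(desk_priors):
    loc_t, conf_t = match_priors(desk_priors, np.zeros((0, 4)), np.zeros(0, dtype=np.int64))
    assert (conf_t == 0).all() and (loc_t == 0).all()


def test_matching_equals_bruteforce_oracle(desk_priors):
    rng = np.random.default_rng(77)
    for _ in range(10):
        n = rng.integers(1, 4)
        xy = rng.uniform(0, 0.6, (n, 2))
        wh = rng.uniform(0.1, 0.4, (n, 2))
        truths = np.concatenate([xy, np.minimum(xy + wh, 1.0)], axis=1)
        labels = np.ones(n, dtype=np.int64)
        loc_t, conf_t = match_priors(desk_priors, truths, labels)

        ious = iou_matrix(truths, desk_priors)
        expect_assign = np.full(len(desk_priors), -1)
        best_t = ious.argmax(axis=0)
        mask = ious.max(axis=0) >= 0.5
        expect_assign[mask] = best_t[mask]
        for t in range(n):
            expect_assign[ious[t].argmax()] = t
        np.testing.assert_array_equal(conf_t > 0, expect_assign >= 0)
        pos = np.where(expect_assign >= 0)[0]
        np.testing.assert_allclose(
            loc_t[pos], encode_boxes(truths[expect_assign[pos]], desk_priors[pos]), atol=1e-12)


def test_encode_decode_identity(desk_priors):
    rng = np.random.default_rng(3)
    xy = rng.uniform(0, 0.5, (40, 2))
    wh = rng.uniform(0.05, 0.5, (40, 2))
    boxes = np.concatenate([xy, np.minimum(xy + wh, 1.0)], axis=1)
    priors = desk_priors[rng.integers(0, len(desk_priors), 40)]
    np.testing.assert_allclose(decode_boxes(encode_boxes(boxes, priors), priors),
                               boxes, atol=1e-6)


# ---------------------------------------------------------------- loss


def reference_multibox_loss(loc, conf, loc_t, conf_t, ratio=3):
    """Straightforward per-image loop reimplementation."""
    n, p, c = conf.shape
    total_pos = max(int((conf_t > 0).sum()), 1)
    loss = 0.0
    for i in range(n):
        pos = conf_t[i] > 0
        for j in np.where(pos)[0]:
            d = loc[i, j] - loc_t[i, j]
            loss += float(np.where(np.abs(d) < 1, 0.5 * d * d, np.abs(d) - 0.5).sum())
        ce = np.empty(p)
        for j in range(p):
            z = conf[i, j] - conf[i, j].max()
            ce[j] = np.log(np.exp(z).sum()) - z[conf_t[i, j]]
        n_neg = min(ratio * max(int(pos.sum()), 1), p - int(pos.sum()))
        neg_order = np.argsort(-np.where(pos, -np.inf, ce))[:n_neg]
        loss += float(ce[pos].sum() + ce[neg_order].sum())
    return loss / total_pos


def test_multibox_loss_matches_independent_reimplementation(desk_priors):
    rng = np.random.default_rng(11)
    n, p, c = 3, len(desk_priors), 2
    conf_t = np.zeros((n, p), dtype=np.int64)
    loc_t = np.zeros((n, p, 4), dtype=np.float32)
    for i in range(n):
        pos = rng.integers(0, p, rng.integers(1, 6))
        conf_t[i, pos] = 1
        loc_t[i, pos] = rng.standard_normal((len(pos), 4))
    loc = nn.Tensor(rng.standard_normal((n, p, 4)).astype(np.float32))
    conf = nn.Tensor(rng.standard_normal((n, p, c)).astype(np.float32))
    got = float(multibox_loss(loc, conf, loc_t, conf_t).data)
    want = reference_multibox_loss(loc.data.astype(np.float64),
                                   conf.data.astype(np.float64), loc_t, conf_t)
    assert got == pytest.approx(want, rel=1e-5)


def test_multibox_loss_limit_cases(desk_priors):
    p = len(desk_priors)
    conf_t = np.zeros((1, p), dtype=np.int64)
    conf_t[0, 10] = 1
    loc_t = np.zeros((1, p, 4), dtype=np.float32)
    loc_t[0, 10] = [0.5, -0.3, 0.2, 0.1]
    # predictions equal to targets with saturated confidences -> loss -> 0
    conf_sat = np.zeros((1, p, 2), dtype=np.float32)
    conf_sat[..., 0] = 40.0
    conf_sat[0, 10] = [0.0, 40.0]
    loss = multibox_loss(nn.Tensor(loc_t), nn.Tensor(conf_sat), loc_t, conf_t)
    assert float(loss.data) == pytest.approx(0.0, abs=1e-6)
    # localization error grows the smooth-L1 term monotonically
    prev = float(loss.data)
    for delta in (0.2, 0.4, 0.8, 1.6):
        loc_bad = loc_t.copy()
        loc_bad[0, 10] += delta
        cur = float(multibox_loss(nn.Tensor(loc_bad), nn.Tensor(conf_sat), loc_t, conf_t).data)
        assert cur > prev
        prev = cur


def test_multibox_loss_no_positives_mines_negatives(desk_priors):
    p = len(desk_priors)
    conf_t = np.zeros((2, p), dtype=np.int64)
    loc_t = np.zeros((2, p, 4), dtype=np.float32)
    rng = np.random.default_rng(0)
    conf = nn.Tensor(rng.standard_normal((2, p, 2)).astype(np.float32), requires_grad=True)
    loc = nn.Tensor(rng.standard_normal((2, p, 4)).astype(np.float32), requires_grad=True)
    loss = multibox_loss(loc, conf, loc_t, conf_t)
    assert float(loss.data) > 0
    loss.backward()
    assert np.abs(loc.grad).sum() == 0  # no localization signal
    assert (np.abs(conf.grad).sum(axis=(1, 2)) > 0).all()  # mined negatives per image
    assert (np.abs(conf.grad) > 0).any(axis=2).sum() <= 2 * 3  # at most ratio*1 per image


def test_multibox_loss_gradients_finite_difference(desk_priors):
    rng = np.random.default_rng(21)
    p = 60
    conf_t = np.zeros((1, p), dtype=np.int64)
    conf_t[0, [3, 17]] = 1
    loc_t = rng.standard_normal((1, p, 4)).astype(np.float32)
    loc = nn.Tensor(rng.standard_normal((1, p, 4)).astype(np.float32), requires_grad=True)
    conf = nn.Tensor(rng.standard_normal((1, p, 2)).astype(np.float32), requires_grad=True)
    loss = multibox_loss(loc, conf, loc_t, conf_t)
    loss.backward()
    eps = 1e-3
    for t in (loc, conf):
        flat = t.data.reshape(-1)
        for idx in rng.integers(0, flat.size, 12):
            orig = flat[idx]
            flat[idx] = orig + eps
            fp_ = float(multibox_loss(loc, conf, loc_t, conf_t).data)
            flat[idx] = orig - eps
            fm = float(multibox_loss(loc, conf, loc_t, conf_t).data)
            flat[idx] = orig
            num = (fp_ - fm) / (2 * eps)
            assert t.grad.reshape(-1)[idx] == pytest.approx(num, abs=3e-3)


# ---------------------------------------------------------------- NMS / decode


def test_nms_suppresses_duplicates_keeps_disjoint():
    boxes = np.array([[0.1, 0.1, 0.4, 0.4], [0.1, 0.1, 0.4, 0.4], [0.6, 0.6, 0.9, 0.9]])
    keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.45)
    assert keep == [0, 2]


def oracle_nms(boxes, scores, thr):
    idx = sorted(range(len(scores)), key=lambda i: -scores[i])
    keep = []
    for i in idx:
        ok = True
        for j in keep:
            if iou_matrix(boxes[i][None], boxes[j][None])[0, 0] > thr:
                ok = False
                break
        if ok:
            keep.append(i)
    return keep


def test_nms_equals_greedy_oracle():
    rng = np.random.default_rng(13)
    for _ in range(20):
        n = rng.integers(1, 30)
        xy = rng.uniform(0, 0.7, (n, 2))
        wh = rng.uniform(0.05, 0.3, (n, 2))
        boxes = np.concatenate([xy, np.minimum(xy + wh, 1.0)], axis=1)
        scores = rng.random(n)
        assert nms(boxes, scores, 0.45, top_k=n) == oracle_nms(boxes, scores, 0.45)


def test_decode_and_nms_contract(desk_priors):
    rng = np.random.default_rng(17)
    p = len(desk_priors)
    loc = rng.standard_normal((p, 4)).astype(np.float32) * 0.3
    conf = rng.standard_normal((p, 2)).astype(np.float32)
    dets = decode_and_nms(loc, conf, desk_priors, conf_threshold=0.3, nms_iou=0.45)
    confs = [d[1] for d in dets]
    assert confs == sorted(confs, reverse=True)
    assert all(c >= 0.3 for c in confs)
    for i in range(len(dets)):
        for j in range(i + 1, len(dets)):
            if dets[i][0] == dets[j][0]:
                v = iou_matrix(dets[i][2][None], dets[j][2][None])[0, 0]
                assert v <= 0.45 + 1e-9


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(schedule=(100, 100))
    with pytest.raises(ValueError):
        TrainConfig(schedule=(200, 100))
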