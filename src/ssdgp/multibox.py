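"""Single-shot multibox machinery: priors, matching, loss, decoding, NMS.

Everything here follows the reference single-shot detector recipe — the
polyp network changes the feature pyramid, not the detection machinery:

* priors tiled per pyramid level at the classic scales/aspect ratios,
* training-time matching at IoU >= 0.5 plus a best-prior guarantee for
  every ground-truth box,
* multibox loss = smooth-L1 localization on positives + softmax
  cross-entropy with hard-negative mining at 3:1,
* decoding with variances (0.1, 0.2) and greedy per-class NMS.

Boxes cross this module as normalized corner coordinates
``(xmin, ymin, xmax, ymax)`` in [0, 1]; the detection record dialect
("image-id class confidence xmin ymin xmax ymax", one per line) carries
pixel coordinates of the annotated frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .netbuilder import DetectionNetwork, PyramidPlan
from .preprocess import AnnotatedImage, Box

__all__ = [
    "TrainConfig", "desk_train_config", "Detection",
    "generate_priors", "encode_boxes", "decode_boxes", "match_priors",
    "multibox_loss", "decode_and_nms", "nms", "Trainer", "detect_images",
    "write_detections", "read_detections", "PAPER_CONF_THRESHOLDS",
]

# the 19-point confidence-threshold grid used by the evaluation protocol
PAPER_CONF_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))

VARIANCES = (0.1, 0.2)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. Defaults are the full-scale recipe: SGD,
    batch 8, base learning rate 5e-4, multi-step decay halfway through
    100k iterations; matching/mining/NMS constants from the reference
    single-shot design."""

    batch_size: int = 8
    base_lr: float = 5e-4
    schedule: tuple[int, ...] = (50_000,)
    total_iterations: int = 100_000
    lr_decay: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 5e-4
    neg_pos_ratio: int = 3
    match_iou: float = 0.5
    nms_iou: float = 0.45
    warmup_iterations: int = 0  # linear ramp from base_lr/10
    augment_flips: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.base_lr, self.total_iterations) <= 0:
            raise ValueError("batch size, learning rate and iterations must be positive")
        if list(self.schedule) != sorted(set(self.schedule)):
            raise ValueError("schedule must be strictly increasing")


def desk_train_config(seed: int = 0, iterations: int = 300) -> TrainConfig:
    """Desk-scale recipe: same machinery, sized for minutes on one CPU.
    The batch-normalized trunk tolerates a much larger step than the
    full-scale network, so training from random weights makes visible
    progress within a few hundred iterations."""
    return TrainConfig(batch_size=8, base_lr=0.01,
                       schedule=(int(iterations * 0.8),),
                       total_iterations=iterations, seed=seed,
                       warmup_iterations=max(iterations // 10, 1))


@dataclass(frozen=True)
class Detection:
    """One detection record: a class, a confidence and a pixel-space box."""

    image_id: str
    class_id: int
    confidence: float
    box: Box


# ---------------------------------------------------------------- priors


def _level_scales(n_levels: int) -> list[tuple[float, float]]:
    """(scale_k, scale_{k+1}) pairs: 0.1 for the finest level, then
    evenly spaced from 0.2 to 0.9."""
    s = [0.1] + list(np.linspace(0.2, 0.9, n_levels - 1))
    s.append(1.05)
    return [(s[i], s[i + 1]) for i in range(n_levels)]


def generate_priors(plan: PyramidPlan) -> np.ndarray:
    """Prior boxes for a plan, normalized corner form, clipped to [0, 1].

    Shape (P, 4); ordering matches the network head layout: levels in
    pyramid order, cells row-major, anchors innermost.
    """
    out = []
    for lv, (sk, sk1) in zip(plan.levels, _level_scales(len(plan.levels))):
        f = lv.spatial
        shapes = [(sk, sk), (np.sqrt(sk * sk1),) * 2]
        for ar in lv.aspect_ratios:
            r = np.sqrt(ar)
            shapes += [(sk * r, sk / r), (sk / r, sk * r)]
        grid = (np.arange(f) + 0.5) / f
        for cy in grid:
            for cx in grid:
                for w, h in shapes:
                    out.append((cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))
    return np.clip(np.array(out, dtype=np.float64), 0.0, 1.0)


def _corner_to_center(boxes: np.ndarray) -> np.ndarray:
    wh = boxes[:, 2:] - boxes[:, :2]
    return np.concatenate([boxes[:, :2] + wh / 2, wh], axis=1)


def encode_boxes(matched: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Corner-form truth boxes -> regression targets relative to priors."""
    g, p = _corner_to_center(matched), _corner_to_center(priors)
    d_xy = (g[:, :2] - p[:, :2]) / (VARIANCES[0] * p[:, 2:])
    d_wh = np.log(g[:, 2:] / p[:, 2:]) / VARIANCES[1]
    return np.concatenate([d_xy, d_wh], axis=1)


def decode_boxes(loc: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Regression outputs -> corner-form boxes (inverse of encode_boxes)."""
    p = _corner_to_center(priors)
    xy = p[:, :2] + loc[:, :2] * VARIANCES[0] * p[:, 2:]
    wh = p[:, 2:] * np.exp(loc[:, 2:] * VARIANCES[1])
    return np.concatenate([xy - wh / 2, xy + wh / 2], axis=1)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of corner-form box arrays, shape (len(a), len(b))."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.clip(rb - lt, 0, None).prod(axis=2)
    area_a = np.clip(a[:, 2:] - a[:, :2], 0, None).prod(axis=1)
    area_b = np.clip(b[:, 2:] - b[:, :2], 0, None).prod(axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def match_priors(priors: np.ndarray, truths: np.ndarray, labels: np.ndarray,
                 iou_threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Assign priors to ground-truth boxes.

    Every truth claims its best-IoU prior (even below threshold); every
    other prior with IoU >= threshold joins the truth it overlaps most.
    Returns ``(loc_targets (P, 4), conf_labels (P,))`` with label 0 for
    background.
    """
    n_priors = len(priors)
    if len(truths) == 0:
        return np.zeros((n_priors, 4)), np.zeros(n_priors, dtype=np.int64)
    ious = iou_matrix(truths, priors)  # (T, P)
    best_truth = ious.argmax(axis=0)
    best_truth_iou = ious.max(axis=0)
    best_prior = ious.argmax(axis=1)  # best prior per truth
    for t, p in enumerate(best_prior):
        best_truth[p] = t
        best_truth_iou[p] = 2.0  # unconditionally positive
    conf = labels[best_truth].astype(np.int64)
    conf[best_truth_iou < iou_threshold] = 0
    loc_t = encode_boxes(truths[best_truth], priors)
    loc_t[conf == 0] = 0.0
    return loc_t, conf


# ---------------------------------------------------------------- loss


def _softmax(z: np.ndarray, axis=-1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def multibox_loss(loc_pred: nn.Tensor, conf_pred: nn.Tensor,
                  loc_t: np.ndarray, conf_t: np.ndarray,
                  neg_pos_ratio: int = 3) -> nn.Tensor:
    """Smooth-L1 localization + mined softmax confidence loss.

    ``loc_pred`` (N, P, 4), ``conf_pred`` (N, P, C); targets are numpy
    arrays from `match_priors`. Normalized by the number of positives
    (clamped to 1). Negatives are mined per image at ``neg_pos_ratio``
    times the positives (at least ratio-many when an image has none), by
    descending background cross-entropy.
    """
    loc, conf = loc_pred.data, conf_pred.data
    n, p, c = conf.shape
    pos = conf_t > 0

    # localization: smooth L1 on positives
    diff = loc - loc_t
    absd = np.abs(diff)
    loc_cell = np.where(absd < 1, 0.5 * diff * diff, absd - 0.5)
    loc_loss = float(loc_cell[pos].sum())

    # per-prior cross-entropy against the assigned label
    zmax = conf.max(axis=2, keepdims=True)
    lse = (zmax + np.log(np.exp(conf - zmax).sum(axis=2, keepdims=True)))[..., 0]
    ce = lse - np.take_along_axis(conf, conf_t[..., None], axis=2)[..., 0]

    # hard-negative mining: rank background priors by their loss
    bg_ce = np.where(pos, -np.inf, ce)
    order = np.argsort(-bg_ce, axis=1)
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(p)[None, :].repeat(n, 0), axis=1)
    n_pos_img = pos.sum(axis=1)
    n_neg_img = np.minimum(neg_pos_ratio * np.maximum(n_pos_img, 1), p - n_pos_img)
    neg = (~pos) & (rank < n_neg_img[:, None])

    sel = pos | neg
    denom = max(int(pos.sum()), 1)
    conf_loss = float(ce[sel].sum())
    total = (loc_loss + conf_loss) / denom

    def backward(gy):
        g = float(gy) / denom
        if loc_pred.requires_grad:
            gloc = np.clip(diff, -1.0, 1.0) * pos[..., None]
            loc_pred._accum(g * gloc.astype(np.float32))
        if conf_pred.requires_grad:
            sm = _softmax(conf, axis=2)
            onehot = np.zeros_like(sm)
            np.put_along_axis(onehot, conf_t[..., None], 1.0, axis=2)
            gconf = (sm - onehot) * sel[..., None]
            conf_pred._accum(g * gconf.astype(np.float32))

    return nn._node(np.float32(total), (loc_pred, conf_pred), backward)


# ---------------------------------------------------------------- decode + NMS


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.45,
        top_k: int = 200) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = list(np.argsort(-scores, kind="stable"))
    keep: list[int] = []
    while order and len(keep) < top_k:
        i = order.pop(0)
        keep.append(i)
        if not order:
            break
        rest = np.array(order)
        ious = iou_matrix(boxes[i][None, :], boxes[rest])[0]
        order = [j for j, v in zip(rest, ious) if v <= iou_threshold]
    return keep


def decode_and_nms(loc: np.ndarray, conf: np.ndarray, priors: np.ndarray,
                   conf_threshold: float = 0.5, nms_iou: float = 0.45,
                   top_k: int = 200) -> list[tuple[int, float, np.ndarray]]:
    """Predictions of one image -> ``(class_id, confidence, box)`` list.

    Results are sorted by descending confidence; per class, no surviving
    pair overlaps beyond ``nms_iou``. Boxes are normalized corner form,
    clipped to [0, 1].
    """
    probs = _softmax(conf, axis=1)
    decoded = np.clip(decode_boxes(loc, priors), 0.0, 1.0)
    results = []
    for cls in range(1, conf.shape[1]):
        scores = probs[:, cls]
        mask = scores >= conf_threshold
        if not mask.any():
            continue
        cand_boxes, cand_scores = decoded[mask], scores[mask]
        for i in nms(cand_boxes, cand_scores, nms_iou, top_k):
            results.append((cls, float(cand_scores[i]), cand_boxes[i]))
    results.sort(key=lambda r: -r[1])
    return results


# ---------------------------------------------------------------- training


class Trainer:
    """SGD training loop over annotated images already resized to the
    network input. Matching targets are precomputed once per image."""

    def __init__(self, net: DetectionNetwork, config: TrainConfig):
        self.net = net
        self.config = config
        self.priors = generate_priors(net.plan)
        self.optimizer = nn.SGD(net.parameters(), lr=config.base_lr,
                                momentum=config.momentum,
                                weight_decay=config.weight_decay)
        self.rng = np.random.default_rng(config.seed)
        self.iteration = 0
        self.loss_history: list[float] = []

    def _prepare(self, anns: list[AnnotatedImage], mirrored: bool = False):
        size = self.net.plan.input_size
        images = np.stack([a.image.transpose(2, 0, 1) for a in anns]).astype(np.float32) / 255.0
        if mirrored:
            images = images[:, :, :, ::-1].copy()
        loc_ts, conf_ts = [], []
        for a in anns:
            if a.image.shape[0] != size or a.image.shape[1] != size:
                raise ValueError(f"image {a.id!r} is not {size}x{size}; resize first")
            truths = np.array([[b.xmin / size, b.ymin / size, b.xmax / size, b.ymax / size]
                               for b in a.boxes]).reshape(-1, 4)
            if mirrored and len(truths):
                truths = np.stack([1 - truths[:, 2], truths[:, 1],
                                   1 - truths[:, 0], truths[:, 3]], axis=1)
            labels = np.ones(len(a.boxes), dtype=np.int64)
            lt, ct = match_priors(self.priors, truths, labels, self.config.match_iou)
            loc_ts.append(lt)
            conf_ts.append(ct)
        return images, np.stack(loc_ts).astype(np.float32), np.stack(conf_ts)

    def _lr_at(self, iteration: int) -> float:
        w = self.config.warmup_iterations
        if iteration < w:
            frac = iteration / w
            return self.config.base_lr * (0.1 + 0.9 * frac)
        decays = sum(iteration >= s for s in self.config.schedule)
        return self.config.base_lr * (self.config.lr_decay ** decays)

    def run(self, anns: list[AnnotatedImage], iterations: int | None = None,
            log_every: int = 0) -> list[float]:
        """Train for ``iterations`` steps (default: config total); returns
        the per-iteration loss history."""
        iterations = iterations or self.config.total_iterations
        images, loc_t, conf_t = self._prepare(anns)
        if self.config.augment_flips:
            images_m, loc_m, conf_m = self._prepare(anns, mirrored=True)
        n = len(anns)
        order = self.rng.permutation(n)
        cursor = 0
        self.net.train(True)
        for _ in range(iterations):
            idx = []
            while len(idx) < self.config.batch_size:
                if cursor == n:
                    order = self.rng.permutation(n)
                    cursor = 0
                idx.append(order[cursor])
                cursor += 1
            idx = np.array(idx)
            batch, blt, bct = images[idx], loc_t[idx], conf_t[idx]
            if self.config.augment_flips:
                flip = self.rng.random(len(idx)) < 0.5
                if flip.any():
                    batch, blt, bct = batch.copy(), blt.copy(), bct.copy()
                    batch[flip] = images_m[idx[flip]]
                    blt[flip] = loc_m[idx[flip]]
                    bct[flip] = conf_m[idx[flip]]
            self.optimizer.lr = self._lr_at(self.iteration)
            loc_p, conf_p = self.net.forward(batch)
            loss = multibox_loss(loc_p, conf_p, blt, bct,
                                 self.config.neg_pos_ratio)
            self.optimizer.zero_grad()
            loss.backward()
            self.optimizer.step()
            self.loss_history.append(float(loss.data))
            self.iteration += 1
            if log_every and self.iteration % log_every == 0:
                recent = self.loss_history[-log_every:]
                print(f"iter {self.iteration:6d}  lr {self.optimizer.lr:.5f}  "
                      f"loss {np.mean(recent):.4f}")
        return self.loss_history


# ---------------------------------------------------------------- inference


def detect_images(net: DetectionNetwork, anns: list[AnnotatedImage],
                  conf_threshold: float = 0.5, nms_iou: float = 0.45) -> list[Detection]:
    """Run the detector on resized annotated images; boxes are restored
    to each image's original frame via its ``source_frame`` metadata."""
    priors = generate_priors(net.plan)
    net.eval()
    out: list[Detection] = []
    for a in anns:
        img = (a.image.transpose(2, 0, 1).astype(np.float32) / 255.0)[None]
        with nn.no_grad():
            loc, conf = net.forward(img)
        frame = a.source_frame or a.frame
        w, h = frame
        for cls, score, box in decode_and_nms(loc.data[0], conf.data[0], priors,
                                              conf_threshold, nms_iou):
            x1, y1, x2, y2 = box * np.array([w, h, w, h])
            x1, y1 = max(x1, 0.0), max(y1, 0.0)
            x2, y2 = min(max(x2, x1 + 1e-6), w), min(max(y2, y1 + 1e-6), h)
            out.append(Detection(a.id, cls, score, Box(x1, y1, x2, y2, frame=frame)))
    return out


def write_detections(dets: list[Detection], path) -> None:
    """One record per line: image-id class confidence xmin ymin xmax ymax."""
    with open(path, "w") as fh:
        for d in dets:
            b = d.box
            fh.write(f"{d.image_id} {d.class_id} {d.confidence:.6f} "
                     f"{b.xmin:.2f} {b.ymin:.2f} {b.xmax:.2f} {b.ymax:.2f}\n")


def read_detections(path, frame: tuple[int, int]) -> list[Detection]:
    """Read the record dialect back; ``frame`` gives the pixel space the
    coordinates refer to."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            image_id, cls, conf, x1, y1, x2, y2 = line.split()
            out.append(Detection(image_id, int(cls), float(conf),
                                 Box(float(x1), float(y1), float(x2), float(y2), frame=frame)))
    return out
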