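"""Order-statistic pooling operators.

Standard max pooling keeps one value per window and discards the rest —
for a 2x2/stride-2 window, three quarters of the activations. The
operators here generalize pooling to an arbitrary order statistic of the
window (rank 1 = max, rank k^2 = min), so that the four pooled maps of a
2x2 window together retain *every* input value: pooling becomes a
lossless spatial-to-channel rearrangement instead of a lossy reduction.

Rank is defined over the sorted multiset of window values, duplicates
kept: the window {3, 3, 1, 0} has second-max 3. This is the only
definition under which the four-way decomposition of an even-sized map
is exactly lossless (multiset equality per channel).

Boundary windows (ceil rounding) may be clipped to fewer than kernel^2
cells; the rank is then clamped to the number of valid cells, so every
output is a genuine input value — zero padding would pollute the min
statistics with artificial zeros.

Arrays are channel-first: ``(..., H, W)`` with any number of leading
batch/channel axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PoolSpec", "rank_pool", "rank_pool_with_indices", "multi_pool", "pool_out_len"]


@dataclass(frozen=True)
class PoolSpec:
    """Geometry of a pooling operation.

    kernel : window edge length in cells
    stride : step between window origins
    padding : implicit border (affects geometry only; padded cells never
        contribute a value, see module docstring)
    mode : output-size rounding, "ceil" (reference-SSD convention,
        75 -> 38) or "floor"
    """

    kernel: int = 2
    stride: int = 2
    padding: int = 0
    mode: str = "ceil"

    def __post_init__(self) -> None:
        if self.kernel < 1:
            raise ValueError(f"kernel must be >= 1, got {self.kernel}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.padding < 0:
            raise ValueError(f"padding must be >= 0, got {self.padding}")
        if self.mode not in ("ceil", "floor"):
            raise ValueError(f"mode must be 'ceil' or 'floor', got {self.mode!r}")


def pool_out_len(n: int, spec: PoolSpec) -> int:
    """Output edge length for an input edge of ``n`` cells."""
    span = n + 2 * spec.padding - spec.kernel
    if span < 0 and spec.padding == 0:
        raise ValueError(f"kernel {spec.kernel} larger than input edge {n}")
    rnd = math.ceil if spec.mode == "ceil" else math.floor
    out = rnd(span / spec.stride) + 1
    # never start a window entirely inside the padding
    if spec.padding > 0 and (out - 1) * spec.stride >= n + spec.padding:
        out -= 1
    return max(out, 1)


def _window_gather(h: int, w: int, spec: PoolSpec):
    """Clipped window cell indices and validity mask.

    Returns (rows, cols, valid) with shapes (oh, k), (ow, k) and
    (oh, ow, k*k); invalid cells are clipped in-range but masked out.
    """
    k, s, p = spec.kernel, spec.stride, spec.padding
    oh, ow = pool_out_len(h, spec), pool_out_len(w, spec)
    taps = np.arange(k)
    rows = np.arange(oh)[:, None] * s - p + taps  # (oh, k)
    cols = np.arange(ow)[:, None] * s - p + taps  # (ow, k)
    vr = (rows >= 0) & (rows < h)
    vc = (cols >= 0) & (cols < w)
    valid = (vr[:, None, :, None] & vc[None, :, None, :]).reshape(oh, ow, k * k)
    if not valid.any(axis=-1).all():
        raise ValueError("pooling window fell entirely outside the input after clipping")
    return rows.clip(0, h - 1), cols.clip(0, w - 1), valid


def rank_pool_with_indices(x: np.ndarray, spec: PoolSpec, rank: int):
    """Rank pooling that also reports which input cell each output came from.

    Returns ``(out, idx)`` where ``idx`` holds flat row-major indices into
    the H*W input plane. Among cells tied at the selected value the first
    in row-major order is reported — the convention used to route
    gradients during training.
    """
    if x.ndim < 2:
        raise ValueError("input needs at least (H, W) axes")
    h, w = x.shape[-2], x.shape[-1]
    if h < 1 or w < 1:
        raise ValueError("input spatial dims must be positive")
    if not 1 <= rank <= spec.kernel ** 2:
        raise ValueError(f"rank {rank} out of range for kernel {spec.kernel}")

    rows, cols, valid = _window_gather(h, w, spec)
    # (..., oh, ow, k, k) -> (..., oh, ow, k*k)
    win = x[..., rows[:, None, :, None], cols[None, :, None, :]]
    win = win.reshape(*win.shape[:-2], spec.kernel ** 2)
    neg_inf = np.finfo(win.dtype).min if np.issubdtype(win.dtype, np.floating) else np.iinfo(win.dtype).min
    masked = np.where(valid, win, neg_inf)
    srt = np.sort(masked, axis=-1)  # ascending; invalid sentinels first
    m = valid.sum(axis=-1)  # valid cells per window, (oh, ow)
    pick = srt.shape[-1] - np.minimum(rank, m)  # clamp rank to clipped multiset
    out = np.take_along_axis(srt, np.broadcast_to(pick, srt.shape[:-1])[..., None], axis=-1)[..., 0]

    first = np.argmax((win == out[..., None]) & valid, axis=-1)  # first row-major tie
    shape_k = first.shape + (spec.kernel,)
    r_sel = np.take_along_axis(
        np.broadcast_to(rows[:, None, :], shape_k), (first // spec.kernel)[..., None], axis=-1
    )[..., 0]
    c_sel = np.take_along_axis(
        np.broadcast_to(cols[None, :, :], shape_k), (first % spec.kernel)[..., None], axis=-1
    )[..., 0]
    idx = r_sel * w + c_sel
    return out, idx


def rank_pool(x: np.ndarray, spec: PoolSpec, rank: int) -> np.ndarray:
    """Pool each window down to its rank-th largest value (1 = max)."""
    out, _ = rank_pool_with_indices(x, spec, rank)
    return out


def multi_pool(x: np.ndarray, spec: PoolSpec | None = None) -> list[np.ndarray]:
    """The four order-statistic poolings of a 2x2 window.

    Returns ``[max, second_max, second_min, min]``. For even spatial dims
    (stride 2, no padding) the four outputs together are a permutation of
    the input, per channel.
    """
    spec = spec or PoolSpec()
    if spec.kernel != 2:
        raise ValueError("multi_pool is defined for 2x2 windows")
    return [rank_pool(x, spec, r) for r in (1, 2, 3, 4)]
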