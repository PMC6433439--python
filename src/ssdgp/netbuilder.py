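"""Declarative construction of the detector variants.

Four architectures share one trunk-plus-pyramid skeleton:

* ``ssd``    — the plain single-shot detector: each pyramid level feeds
  its detection head directly.
* ``ssd-p``  — every level is widened by a *pooling module*: the four
  order-statistic poolings (max / second-max / second-min / min) of a
  2x-resolution source layer, each through a 1x1 convolution and batch
  norm, concatenated onto the level.
* ``ssd-d``  — every level (except the topmost, which has no upper
  neighbor) is widened by a *deconvolution module*: a stride-2 kernel-2
  transposed convolution of the next-higher pyramid level, batch-normed
  and concatenated.
* ``ssd-pd`` — both modules together (the full gastric-polyp network).

Plans are declarative: `default_plan` wires levels, pooling sources and
deconvolution sources; `build_network` realizes a plan as a trainable
network. Two canonical geometries exist — input 300 with the six
classic pyramid levels (Conv4_3 ... Conv9_2 at 38/19/10/5/3/1 cells),
and a desk-scale input 96 with four levels (12/6/3/1) whose trunk adds
batch norm so it trains from random initialization in minutes on a CPU.

Branch widths (not dictated by the architecture itself): each of the
four pooling branches contributes base_channels/4 and the deconvolution
branch base_channels/2, so a fully widened level is 2.5x its plain
width — in line with the roughly 50% model growth the full method
reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .pooling import PoolSpec

__all__ = ["LevelSpec", "PyramidPlan", "default_plan", "build_network",
           "force_spatial", "DetectionNetwork", "VARIANTS"]

VARIANTS = ("ssd", "ssd-p", "ssd-d", "ssd-pd")


@dataclass(frozen=True)
class LevelSpec:
    name: str
    spatial: int          # feature-map edge length in cells
    base_channels: int    # channels of the plain (identity) level
    pool_source: str      # 2x-resolution layer feeding the pooling module
    deconv_source: str | None  # upper pyramid neighbor, None for the top level
    aspect_ratios: tuple[int, ...]  # extra prior aspect ratios (besides 1)

    @property
    def boxes_per_cell(self) -> int:
        return 2 + 2 * len(self.aspect_ratios)


@dataclass(frozen=True)
class PyramidPlan:
    variant: str
    input_size: int
    channel_scale: float
    levels: tuple[LevelSpec, ...]
    trunk_batchnorm: bool

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        sizes = [lv.spatial for lv in self.levels]
        if sizes != sorted(sizes, reverse=True) or len(set(sizes)) != len(sizes):
            raise ValueError("pyramid levels must have strictly decreasing spatial size")
        if self.levels[-1].deconv_source is not None:
            raise ValueError("the topmost pyramid level has no upper neighbor to deconvolve")

    def level(self, name: str) -> LevelSpec:
        for lv in self.levels:
            if lv.name == name:
                return lv
        raise KeyError(name)

    # --- branch bookkeeping -------------------------------------------
    def pooling_branch_channels(self, lv: LevelSpec) -> int:
        return max(lv.base_channels // 4, 1)

    def deconv_branch_channels(self, lv: LevelSpec) -> int:
        return max(lv.base_channels // 2, 1)

    def head_channels(self, lv: LevelSpec) -> int:
        """Channels entering the level's detection head (identity + branches)."""
        c = lv.base_channels
        if self.variant in ("ssd-p", "ssd-pd"):
            c += 4 * self.pooling_branch_channels(lv)
        if self.variant in ("ssd-d", "ssd-pd") and lv.deconv_source is not None:
            c += self.deconv_branch_channels(lv)
        return c

    def serialize(self) -> str:
        lines = [f"variant = {self.variant}",
                 f"input_size = {self.input_size}",
                 f"channel_scale = {self.channel_scale}",
                 f"trunk_batchnorm = {int(self.trunk_batchnorm)}"]
        for lv in self.levels:
            lines.append(
                f"level = {lv.name} {lv.spatial} {lv.base_channels} "
                f"{lv.pool_source} {lv.deconv_source or '-'} "
                f"{','.join(map(str, lv.aspect_ratios))}"
            )
        return "\n".join(lines) + "\n"

    @staticmethod
    def deserialize(text: str) -> "PyramidPlan":
        kv, levels = {}, []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "level":
                name, spatial, ch, psrc, dsrc, ars = val.split()
                levels.append(LevelSpec(name, int(spatial), int(ch), psrc,
                                        None if dsrc == "-" else dsrc,
                                        tuple(int(a) for a in ars.split(",") if a)))
            else:
                kv[key] = val
        return PyramidPlan(variant=kv["variant"], input_size=int(kv["input_size"]),
                           channel_scale=float(kv["channel_scale"]),
                           levels=tuple(levels), trunk_batchnorm=bool(int(kv["trunk_batchnorm"])))


def _scaled(c: int, scale: float) -> int:
    """Scale a channel count, keeping it a positive multiple of 4."""
    return max(4 * round(c * scale / 4), 4)


# Full-scale trunk: VGG16 stage widths / conv counts; desk scale stops at
# stage 4 and uses two convs per stage.
_FULL_LEVELS = (
    # name, spatial@300, base_channels, pool_source, deconv_source, aspect ratios
    ("conv4_3", 38, 512, "conv3_3", "fc7", (2,)),
    ("fc7", 19, 1024, "conv4_3", "conv6_2", (2, 3)),
    ("conv6_2", 10, 512, "fc7", "conv7_2", (2, 3)),
    ("conv7_2", 5, 256, "conv6_2", "conv8_2", (2, 3)),
    ("conv8_2", 3, 256, "conv7_2", "conv9_2", (2,)),
    ("conv9_2", 1, 256, "conv8_2", None, (2,)),
)
_DESK_LEVELS = (
    ("conv4_3", 12, 512, "conv3_3", "fc7", (2,)),
    ("fc7", 6, 1024, "conv4_3", "conv6_2", (2, 3)),
    ("conv6_2", 3, 512, "fc7", "conv7_2", (2, 3)),
    ("conv7_2", 1, 256, "conv6_2", None, (2,)),
)


def default_plan(variant: str = "ssd-pd", input_size: int = 300,
                 channel_scale: float = 1.0) -> PyramidPlan:
    """The canonical wiring for input 300 (6 levels) or 96 (desk scale, 4)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if not 0 < channel_scale <= 1:
        raise ValueError("channel_scale must be in (0, 1]")
    if input_size == 300:
        raw, trunk_bn = _FULL_LEVELS, False
    elif input_size == 96:
        raw, trunk_bn = _DESK_LEVELS, True
    else:
        raise ValueError("canonical input sizes are 300 (full) and 96 (desk scale)")
    levels = tuple(
        LevelSpec(name, sp, _scaled(ch, channel_scale), psrc, dsrc, ars)
        for name, sp, ch, psrc, dsrc, ars in raw
    )
    return PyramidPlan(variant=variant, input_size=input_size,
                       channel_scale=channel_scale, levels=levels,
                       trunk_batchnorm=trunk_bn)


def force_spatial(x: Tensor, target: int) -> Tensor:
    """Reconcile a branch output with its level's grid (<= 2 cells off):
    center-crop when larger, bilinear-resize when smaller."""
    edge = x.shape[-1]
    if abs(edge - target) > 2:
        raise ValueError(f"spatial mismatch {edge} vs {target} exceeds the 2-cell "
                         "tolerance; the pyramid plan is mis-wired")
    if edge == target:
        return x
    if edge > target:
        return nn.center_crop(x, target, target)
    return nn.bilinear_resize(x, target, target)


# ---------------------------------------------------------------- network


class _ConvBlock(nn.Module):
    """conv3x3 -> (optional BN) -> ReLU trunk unit."""

    def __init__(self, cin, cout, rng, batchnorm, stride=1, padding=1,
                 kernel=3, dilation=1):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, rng, stride=stride,
                              padding=padding, dilation=dilation)
        self.bn = nn.BatchNorm2d(cout) if batchnorm else None

    def parameters(self):
        return self.conv.parameters() + (self.bn.parameters() if self.bn else [])

    def __call__(self, x):
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return nn.relu(y)


class DetectionNetwork:
    """A realized pyramid plan: image in, per-prior (offsets, scores) out."""

    def __init__(self, plan: PyramidPlan, num_classes: int, seed: int = 0):
        self.plan = plan
        self.num_classes = num_classes
        self.seed = seed
        rng = np.random.default_rng(seed)
        scale = plan.channel_scale
        bn = plan.trunk_batchnorm
        self._modules: dict[str, nn.Module] = {}
        m = self._modules

        def C(name, *args, **kw):
            m[name] = _ConvBlock(*args, rng=rng, batchnorm=bn, **kw)
            return m[name]

        full = plan.input_size == 300
        s = lambda c: _scaled(c, scale)
        reps = (2, 2, 3, 3) if full else (2, 2, 2, 2)
        widths = (s(64), s(128), s(256), s(512))
        # stages 1..4; the last conv of stage 3 is "conv3_3", of stage 4 "conv4_3"
        cin = 3
        for stage, (rep, w) in enumerate(zip(reps, widths), start=1):
            for r in range(1, rep + 1):
                C(f"conv{stage}_{r}", cin, w, )
                cin = w
        if full:
            # stage 5 + dilated fc6/fc7, as in the classic 300-input trunk
            for r in range(1, 4):
                C(f"conv5_{r}", cin, s(512))
            C("fc6", s(512), s(1024), padding=6, dilation=6)
            m["fc7"] = _ConvBlock(s(1024), s(1024), rng=rng, batchnorm=bn,
                                  kernel=1, padding=0)
        else:
            C("fc6", cin, s(1024))
            m["fc7"] = _ConvBlock(s(1024), s(1024), rng=rng, batchnorm=bn,
                                  kernel=1, padding=0)
        # extra feature layers
        C("conv6_1", s(1024), s(256), kernel=1, padding=0)
        C("conv6_2", s(256), s(512), stride=2, padding=1)
        if full:
            C("conv7_1", s(512), s(128), kernel=1, padding=0)
            C("conv7_2", s(128), s(256), stride=2, padding=1)
            C("conv8_1", s(256), s(128), kernel=1, padding=0)
            C("conv8_2", s(128), s(256), padding=0)
            C("conv9_1", s(256), s(128), kernel=1, padding=0)
            C("conv9_2", s(128), s(256), padding=0)
        else:
            C("conv7_1", s(512), s(128), kernel=1, padding=0)
            C("conv7_2", s(128), s(256), padding=0)

        m["l2norm"] = nn.L2NormScale(plan.level("conv4_3").base_channels)

        # expansion branches
        pool_on = plan.variant in ("ssd-p", "ssd-pd")
        deconv_on = plan.variant in ("ssd-d", "ssd-pd")
        for lv in plan.levels:
            if pool_on:
                pc = plan.pooling_branch_channels(lv)
                src_c = self._source_channels(lv.pool_source)
                for r in range(1, 5):
                    m[f"{lv.name}_pool{r}_conv"] = nn.Conv2d(src_c, pc, 1, rng)
                    m[f"{lv.name}_pool{r}_bn"] = nn.BatchNorm2d(pc)
            if deconv_on and lv.deconv_source is not None:
                dc = plan.deconv_branch_channels(lv)
                src_c = plan.level(lv.deconv_source).base_channels
                m[f"{lv.name}_deconv"] = nn.ConvTranspose2d(src_c, dc, 2, rng, stride=2)
                m[f"{lv.name}_deconv_bn"] = nn.BatchNorm2d(dc)

        # detection heads; the confidence head starts biased toward
        # background so untrained networks are not swamped by mined
        # negatives in the first iterations
        for lv in plan.levels:
            hc = plan.head_channels(lv)
            m[f"{lv.name}_loc"] = nn.Conv2d(hc, lv.boxes_per_cell * 4, 3, rng, padding=1)
            conf = nn.Conv2d(hc, lv.boxes_per_cell * num_classes, 3, rng, padding=1)
            conf.bias.data[::num_classes] = 4.0  # background logit per anchor
            m[f"{lv.name}_conf"] = conf

        self.train(True)

    def _source_channels(self, name: str) -> int:
        """Channel width of a pooling-source feature map (a pyramid level
        or the stage-3 trunk output)."""
        if name == "conv3_3":
            return _scaled(256, self.plan.channel_scale)
        return self.plan.level(name).base_channels

    # --- mode / parameters -------------------------------------------
    def train(self, flag: bool = True):
        self.training = flag
        for mod in self._modules.values():
            mod.training = flag
            for sub in vars(mod).values():
                if isinstance(sub, nn.Module):
                    sub.training = flag
        return self

    def eval(self):
        return self.train(False)

    def parameters(self) -> list[nn.Parameter]:
        out = []
        for mod in self._modules.values():
            out.extend(mod.parameters())
        return out

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # --- persistence --------------------------------------------------
    def save(self, path) -> None:
        arrays = {"__plan__": np.frombuffer(self.plan.serialize().encode(), dtype=np.uint8),
                  "__num_classes__": np.array([self.num_classes])}
        for name, mod in self._modules.items():
            for k, v in mod.state_arrays().items():
                arrays[f"{name}/{k}"] = v
            for sk, sub in vars(mod).items():
                if isinstance(sub, nn.Module):
                    for k, v in sub.state_arrays().items():
                        arrays[f"{name}/{sk}/{k}"] = v
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DetectionNetwork":
        with np.load(path) as z:
            plan = PyramidPlan.deserialize(bytes(z["__plan__"]).decode())
            num_classes = int(z["__num_classes__"][0])
            net = cls(plan, num_classes)
            grouped: dict[str, dict[str, np.ndarray]] = {}
            for key in z.files:
                if key.startswith("__"):
                    continue
                mod_name, _, rest = key.partition("/")
                grouped.setdefault(mod_name, {})[rest] = z[key]
        for name, arrays in grouped.items():
            mod = net._modules[name]
            direct = {k: v for k, v in arrays.items() if "/" not in k}
            if direct:
                mod.load_state_arrays(direct)
            subs: dict[str, dict[str, np.ndarray]] = {}
            for k, v in arrays.items():
                if "/" in k:
                    sub, _, kk = k.partition("/")
                    subs.setdefault(sub, {})[kk] = v
            for sub, sub_arrays in subs.items():
                getattr(mod, sub).load_state_arrays(sub_arrays)
        return net

    # --- forward ------------------------------------------------------
    def _trunk(self, x: Tensor) -> dict[str, Tensor]:
        m = self._modules
        full = self.plan.input_size == 300
        feats: dict[str, Tensor] = {}
        reps = (2, 2, 3, 3) if full else (2, 2, 2, 2)
        h = x
        for stage, rep in enumerate(reps, start=1):
            for r in range(1, rep + 1):
                h = m[f"conv{stage}_{r}"](h)
            feats[f"conv{stage}_{rep}"] = h
            if stage < 4:
                h = nn.max_pool2d(h)
        feats["conv3_3"] = feats.pop(f"conv3_{reps[2]}")
        feats["conv4_3"] = feats.pop(f"conv4_{reps[3]}")
        h = nn.max_pool2d(feats["conv4_3"])
        if full:
            for r in range(1, 4):
                h = m[f"conv5_{r}"](h)
            h = nn.max_pool2d(h, kernel=3, stride=1, padding=1)
        h = m["fc6"](h)
        h = m["fc7"](h)
        feats["fc7"] = h
        h = m["conv6_2"](m["conv6_1"](h))
        feats["conv6_2"] = h
        h = m["conv7_2"](m["conv7_1"](h))
        feats["conv7_2"] = h
        if full:
            h = m["conv8_2"](m["conv8_1"](h))
            feats["conv8_2"] = h
            h = m["conv9_2"](m["conv9_1"](h))
            feats["conv9_2"] = h
        return feats

    def _expanded_level(self, lv: LevelSpec, feats: dict[str, Tensor]) -> Tensor:
        m = self._modules
        base = feats[lv.name]
        if lv.name == "conv4_3":
            base = m["l2norm"](base)
        parts = [base]
        if self.plan.variant in ("ssd-p", "ssd-pd"):
            src = feats[lv.pool_source]
            spec = PoolSpec()  # 2x2, stride 2, ceil
            for r in range(1, 5):
                pooled = nn.rank_pool2d(src, spec, r)
                pooled = force_spatial(pooled, lv.spatial)
                pooled = m[f"{lv.name}_pool{r}_bn"](m[f"{lv.name}_pool{r}_conv"](pooled))
                parts.append(pooled)
        if self.plan.variant in ("ssd-d", "ssd-pd") and lv.deconv_source is not None:
            src = feats[lv.deconv_source]
            up = m[f"{lv.name}_deconv"](src)
            up = force_spatial(up, lv.spatial)
            parts.append(m[f"{lv.name}_deconv_bn"](up))
        if len(parts) == 1:
            return parts[0]
        return nn.concat_channels(parts)

    def forward(self, images: np.ndarray) -> tuple[Tensor, Tensor]:
        """images (N, 3, S, S) in [0, 1] -> (loc (N, P, 4), conf (N, P, C))."""
        if images.ndim != 4 or images.shape[1] != 3 or images.shape[2] != self.plan.input_size:
            raise ValueError(f"expected (N, 3, {self.plan.input_size}, {self.plan.input_size}) input, "
                             f"got {images.shape}")
        x = Tensor(images)
        feats = self._trunk(x)
        locs, confs = [], []
        for lv in self.plan.levels:
            ex = self._expanded_level(lv, feats)
            if ex.shape[-1] != lv.spatial:
                raise ValueError(f"level {lv.name}: got edge {ex.shape[-1]}, plan says {lv.spatial}")
            locs.append(nn.to_box_layout(self._modules[f"{lv.name}_loc"](ex), 4))
            confs.append(nn.to_box_layout(self._modules[f"{lv.name}_conf"](ex), self.num_classes))
        return nn.concat_rows(locs), nn.concat_rows(confs)

    __call__ = forward


def build_network(plan: PyramidPlan, num_classes: int, seed: int = 0) -> DetectionNetwork:
    """Realize a pyramid plan as a trainable detection network."""
    return DetectionNetwork(plan, num_classes, seed=seed)
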