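"""Closed-form accounting for YoloV8seg variants and an elongated-target variant.

This module reconstructs the layer graph of the YoloV8seg family (n/s/m/l/x)
and of an improved n-variant for elongated roots — two extra stride-2
downsampling stages in the backbone plus two large-target detect/segment
heads at the new coarser strides (64 and 128) — and counts enumerated
modules, trainable parameters and FLOPs without ever instantiating a
network.  It never trains or runs inference.

Counting conventions (the family's reporting conventions, reproduced here):

* *Layers* enumerates the flattened module tree: every container and leaf
  module counts once, the activation is a single shared instance counted
  once for the whole model, and the two top-level containers (model + its
  sequential graph) are included.
* *Parameters* sums trainable conv/BN/bias tensors plus the 16 fixed
  weights of the distribution-focal decoding conv (which carries no
  gradient, hence ``gradients = params - 16``).
* *FLOPs* are twice the multiply-accumulate count at an explicit input size
  (640 x 640 by default, the ecosystem's reporting size): convolutions
  count ``out_elems * (c_in/groups * k^2 + bias)``, batch norm counts
  ``4 * numel``, and pooling / nearest upsampling / concatenation /
  activations count zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

__all__ = [
    "ArchitectureSpec",
    "CountReport",
    "LayerSpec",
    "TrainingBox",
    "VARIANTS",
    "build_spec",
    "count_flops",
    "count_layers",
    "count_params",
    "export_model_config",
    "import_model_config",
    "layer_param_count",
    "select_training_targets",
]

#: (depth multiplier, width multiplier, max channels) per family variant
VARIANTS: dict[str, tuple[float, float, int]] = {
    "n": (0.33, 0.25, 1024),
    "s": (0.33, 0.50, 1024),
    "m": (0.67, 0.75, 768),
    "l": (1.00, 1.00, 512),
    "x": (1.00, 1.25, 512),
}

_KINDS = ("conv", "c2f", "sppf", "upsample", "concat", "segment_head")

#: model container + sequential graph + one shared activation instance
_TOP_LEVEL_MODULES = 3

_REG_MAX = 16  # distribution-focal bins per box side


@dataclass(frozen=True)
class LayerSpec:
    """One module of the flattened layer graph.

    ``from_`` holds input layer indices (``-1`` = the input image, only
    valid for layer 0).  ``out_ch`` is the realized output channel count;
    for ``concat``/``upsample`` it is derived and stored as 0.  ``repeats``
    is the bottleneck count inside a ``c2f`` block.
    """

    kind: str
    from_: tuple[int, ...]
    out_ch: int = 0
    kernel: int = 1
    stride: int = 1
    repeats: int = 1
    shortcut: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind '{self.kind}'")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.kind in ("conv", "c2f", "sppf") and self.out_ch <= 0:
            raise ValueError(f"{self.kind} layer needs positive out_ch")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer graph of one segmentation-network variant."""

    variant: str
    depth_mult: float
    width_mult: float
    max_channels: int
    num_classes: int
    layers: tuple[LayerSpec, ...]
    head_strides: tuple[int, ...]
    mask_protos: int = 32  # mask coefficients per instance
    proto_channels: int = 64  # realized prototype-branch width


@dataclass(frozen=True)
class CountReport:
    """Module/parameter/FLOP counts; FLOPs always record their input size."""

    layer_count: int
    params: int
    gradients: int
    flops: int
    input_hw: tuple[int, int]

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def gradients_m(self) -> float:
        return self.gradients / 1e6

    @property
    def flops_g(self) -> float:
        return self.flops / 1e9


@dataclass(frozen=True)
class TrainingBox:
    """A ground-truth target box (width, height in pixels); degenerate
    boxes are representable and handled by the selection filter."""

    w: float
    h: float


def _make_divisible(x: float, divisor: int = 8) -> int:
    return math.ceil(x / divisor) * divisor


class _Acc:
    """Running totals while walking a layer graph."""

    def __init__(self) -> None:
        self.params = 0
        self.modules = 0
        self.ops = 0  # multiply-accumulate-equivalent units; flops = 2*ops

    def conv2d(self, c1, c2, k, h, w, bias=False):
        self.params += k * k * c1 * c2 + (c2 if bias else 0)
        self.modules += 1
        self.ops += h * w * c2 * (c1 * k * k + (1 if bias else 0))

    def bn(self, c, h, w):
        self.params += 2 * c
        self.modules += 1
        self.ops += 4 * c * h * w

    def cbs(self, c1, c2, k, h, w):
        """Conv+BN+SiLU composite (activation instance is shared model-wide)."""
        self.modules += 1  # composite container
        self.conv2d(c1, c2, k, h, w)
        self.bn(c2, h, w)

    def plain(self, n=1):
        self.modules += n


def _acc_c2f(a: _Acc, c1: int, c2: int, n: int, h: int, w: int) -> None:
    c = c2 // 2
    a.plain(1)  # block container
    a.cbs(c1, 2 * c, 1, h, w)
    a.cbs((2 + n) * c, c2, 1, h, w)
    a.plain(1)  # bottleneck list container
    for _ in range(n):
        a.plain(1)  # bottleneck container
        a.cbs(c, c, 3, h, w)
        a.cbs(c, c, 3, h, w)


def _acc_sppf(a: _Acc, c1: int, c2: int, h: int, w: int) -> None:
    c = c1 // 2
    a.plain(1)
    a.cbs(c1, c, 1, h, w)
    a.cbs(4 * c, c2, 1, h, w)
    a.plain(1)  # max-pool (zero ops)


def _acc_segment_head(
    a: _Acc,
    nc: int,
    nm: int,
    npr: int,
    chs: list[int],
    hws: list[tuple[int, int]],
) -> None:
    c_box = max(16, chs[0] // 4, _REG_MAX * 4)
    c_cls = max(chs[0], min(nc, 100))
    c_msk = max(chs[0] // 4, nm)
    a.plain(1)  # head container
    a.plain(1)  # box-branch list
    for ch, (h, w) in zip(chs, hws):
        a.plain(1)
        a.cbs(ch, c_box, 3, h, w)
        a.cbs(c_box, c_box, 3, h, w)
        a.conv2d(c_box, 4 * _REG_MAX, 1, h, w, bias=True)
    a.plain(1)  # class-branch list
    for ch, (h, w) in zip(chs, hws):
        a.plain(1)
        a.cbs(ch, c_cls, 3, h, w)
        a.cbs(c_cls, c_cls, 3, h, w)
        a.conv2d(c_cls, nc, 1, h, w, bias=True)
    # distribution-focal decoding conv: fixed, gradient-free weights
    a.plain(2)
    a.params += _REG_MAX
    # prototype-mask branch hangs off the finest level
    h0, w0 = hws[0]
    a.plain(1)
    a.cbs(chs[0], npr, 3, h0, w0)
    a.params += npr * npr * 4 + npr  # 2x2 stride-2 transposed conv, with bias
    a.modules += 1
    a.ops += (2 * h0) * (2 * w0) * npr * (npr * 4 + 1)
    a.cbs(npr, npr, 3, 2 * h0, 2 * w0)
    a.cbs(npr, nm, 1, 2 * h0, 2 * w0)
    a.plain(1)  # mask-coefficient list
    for ch, (h, w) in zip(chs, hws):
        a.plain(1)
        a.cbs(ch, c_msk, 3, h, w)
        a.cbs(c_msk, c_msk, 3, h, w)
        a.conv2d(c_msk, nm, 1, h, w, bias=True)


def _base_layers(variant: str, nc: int) -> tuple[tuple[LayerSpec, ...], int]:
    """Standard segmentation layout: CSP backbone + PAN neck, heads at 8/16/32."""
    gd, gw, mc = VARIANTS[variant]

    def ch(c: int) -> int:
        return _make_divisible(min(c, mc) * gw)

    def rep(n: int) -> int:
        return max(round(n * gd), 1)

    L = LayerSpec
    layers = (
        L("conv", (-1,), ch(64), 3, 2),
        L("conv", (0,), ch(128), 3, 2),
        L("c2f", (1,), ch(128), repeats=rep(3), shortcut=True),
        L("conv", (2,), ch(256), 3, 2),
        L("c2f", (3,), ch(256), repeats=rep(6), shortcut=True),
        L("conv", (4,), ch(512), 3, 2),
        L("c2f", (5,), ch(512), repeats=rep(6), shortcut=True),
        L("conv", (6,), ch(1024), 3, 2),
        L("c2f", (7,), ch(1024), repeats=rep(3), shortcut=True),
        L("sppf", (8,), ch(1024), kernel=5),
        L("upsample", (9,)),
        L("concat", (10, 6)),
        L("c2f", (11,), ch(512), repeats=rep(3)),
        L("upsample", (12,)),
        L("concat", (13, 4)),
        L("c2f", (14,), ch(256), repeats=rep(3)),
        L("conv", (15,), ch(256), 3, 2),
        L("concat", (16, 12)),
        L("c2f", (17,), ch(512), repeats=rep(3)),
        L("conv", (18,), ch(512), 3, 2),
        L("concat", (19, 9)),
        L("c2f", (20,), ch(1024), repeats=rep(3)),
        L("segment_head", (15, 18, 21)),
    )
    return layers, ch(256)


# Widths and repeats of the two added stages and their fusion blocks are not
# derivable from the family's scaling rules; they are fixed constants of the
# improved variant, reconciled against its published accounting (431 layers,
# 10.45 M parameters, 13.8 GFLOPs at 640).
_IMPROVED_P6_CH = 352
_IMPROVED_P7_CH = 160
_IMPROVED_NECK_CH = 256
_IMPROVED_STAGE_REPEATS = 1
_IMPROVED_TOPDOWN_REPEATS = 2  # the two fusion blocks feeding the new levels


def _improved_layers(nc: int) -> tuple[tuple[LayerSpec, ...], int]:
    """n-variant backbone extended to stride 128 with five pyramid heads."""
    base, npr = _base_layers("n", nc)
    c6, c7, cn = _IMPROVED_P6_CH, _IMPROVED_P7_CH, _IMPROVED_NECK_CH
    rs, rt = _IMPROVED_STAGE_REPEATS, _IMPROVED_TOPDOWN_REPEATS
    L = LayerSpec
    layers = base[:10] + (
        L("conv", (9,), c6, 3, 2),  # 10: P6 downsample
        L("c2f", (10,), c6, repeats=rs, shortcut=True),  # 11
        L("conv", (11,), c7, 3, 2),  # 12: P7 downsample
        L("c2f", (12,), c7, repeats=rs, shortcut=True),  # 13
        L("upsample", (13,)),  # 14
        L("concat", (14, 11)),  # 15
        L("c2f", (15,), cn, repeats=rt),  # 16: top-down P6
        L("upsample", (16,)),  # 17
        L("concat", (17, 9)),  # 18
        L("c2f", (18,), cn, repeats=rt),  # 19: top-down P5
        L("upsample", (19,)),  # 20
        L("concat", (20, 6)),  # 21
        L("c2f", (21,), 128, repeats=1),  # 22: top-down P4
        L("upsample", (22,)),  # 23
        L("concat", (23, 4)),  # 24
        L("c2f", (24,), 64, repeats=1),  # 25: P3 head input
        L("conv", (25,), 64, 3, 2),  # 26
        L("concat", (26, 22)),  # 27
        L("c2f", (27,), 128, repeats=1),  # 28: P4 head input
        L("conv", (28,), 128, 3, 2),  # 29
        L("concat", (29, 19)),  # 30
        L("c2f", (30,), 256, repeats=1),  # 31: P5 head input
        L("conv", (31,), 256, 3, 2),  # 32
        L("concat", (32, 16)),  # 33
        L("c2f", (33,), cn, repeats=1),  # 34: P6 head input
        L("conv", (34,), cn, 3, 2),  # 35
        L("concat", (35, 13)),  # 36
        L("c2f", (36,), cn, repeats=1),  # 37: P7 head input
        L("segment_head", (25, 28, 31, 34, 37)),  # 38
    )
    return layers, npr


def build_spec(variant: str) -> ArchitectureSpec:
    """Build the layer graph of a family variant or of ``improved_n``.

    Base variants have detect/segment heads at strides 8/16/32; the
    improved variant adds two stride-2 backbone stages and two large-target
    heads, for head strides 8/16/32/64/128.
    """
    nc = 2  # primary root, lateral root
    if variant in VARIANTS:
        layers, npr = _base_layers(variant, nc)
        gd, gw, mc = VARIANTS[variant]
        strides = (8, 16, 32)
    elif variant == "improved_n":
        layers, npr = _improved_layers(nc)
        gd, gw, mc = VARIANTS["n"]
        strides = (8, 16, 32, 64, 128)
    else:
        raise ValueError(
            f"unknown variant '{variant}'; expected one of "
            f"{sorted(VARIANTS)} or 'improved_n'"
        )
    return ArchitectureSpec(
        variant=variant,
        depth_mult=gd,
        width_mult=gw,
        max_channels=mc,
        num_classes=nc,
        layers=layers,
        head_strides=strides,
        proto_channels=npr,
    )


def _walk(spec: ArchitectureSpec, input_hw: tuple[int, int]) -> _Acc:
    """Propagate shapes through the graph and accumulate all counts."""
    a = _Acc()
    a.plain(_TOP_LEVEL_MODULES)
    shapes: list[tuple[int, int, int]] = []  # (channels, h, w) per layer

    def shape_of(idx: int) -> tuple[int, int, int]:
        if idx == -1:
            return (3, input_hw[0], input_hw[1])
        return shapes[idx]

    for layer in spec.layers:
        ins = [shape_of(i) for i in layer.from_]
        c1, h, w = ins[0]
        if layer.kind == "conv":
            ho, wo = math.ceil(h / layer.stride), math.ceil(w / layer.stride)
            a.cbs(c1, layer.out_ch, layer.kernel, ho, wo)
            shapes.append((layer.out_ch, ho, wo))
        elif layer.kind == "c2f":
            _acc_c2f(a, c1, layer.out_ch, layer.repeats, h, w)
            shapes.append((layer.out_ch, h, w))
        elif layer.kind == "sppf":
            _acc_sppf(a, c1, layer.out_ch, h, w)
            shapes.append((layer.out_ch, h, w))
        elif layer.kind == "upsample":
            a.plain(1)
            shapes.append((c1, 2 * h, 2 * w))
        elif layer.kind == "concat":
            a.plain(1)
            shapes.append((sum(s[0] for s in ins), h, w))
        else:  # segment_head
            _acc_segment_head(
                a,
                spec.num_classes,
                spec.mask_protos,
                spec.proto_channels,
                [s[0] for s in ins],
                [(s[1], s[2]) for s in ins],
            )
            shapes.append((0, h, w))
    return a


def _report(spec: ArchitectureSpec, input_hw: tuple[int, int]) -> CountReport:
    a = _walk(spec, input_hw)
    has_head = any(l.kind == "segment_head" for l in spec.layers)
    grads = a.params - (_REG_MAX if has_head else 0)
    return CountReport(
        layer_count=a.modules,
        params=a.params,
        gradients=grads,
        flops=2 * a.ops,
        input_hw=input_hw,
    )


def count_params(spec: ArchitectureSpec, input_hw: tuple[int, int] = (640, 640)) -> CountReport:
    """Closed-form parameter (and companion) counts for a layer graph."""
    return _report(spec, input_hw)


def count_layers(spec: ArchitectureSpec) -> int:
    """Enumerated module count under the flattened-graph convention."""
    return _report(spec, (640, 640)).layer_count


def count_flops(spec: ArchitectureSpec, input_hw: tuple[int, int] = (640, 640)) -> CountReport:
    """FLOP count evaluated analytically at ``input_hw`` (default 640 x 640)."""
    return _report(spec, input_hw)


def layer_param_count(layer: LayerSpec, in_ch: int) -> int:
    """Parameters of a single layer given its input channel count.

    Useful for additivity checks; e.g. one conv composite with k=3,
    c_in=16, c_out=32 has ``3*3*16*32 + 2*32 = 4672`` parameters.
    """
    a = _Acc()
    if layer.kind == "conv":
        a.cbs(in_ch, layer.out_ch, layer.kernel, 1, 1)
    elif layer.kind == "c2f":
        _acc_c2f(a, in_ch, layer.out_ch, layer.repeats, 1, 1)
    elif layer.kind == "sppf":
        _acc_sppf(a, in_ch, layer.out_ch, 1, 1)
    elif layer.kind in ("upsample", "concat"):
        pass
    else:
        raise ValueError("use count_params for head-bearing graphs")
    return a.params


def select_training_targets(
    boxes: list[TrainingBox],
    enforce_aspect_limit: bool = True,
    limit: float = 100.0,
) -> list[TrainingBox]:
    """Filter ground-truth boxes for training.

    Boxes with non-positive width or height are always removed.  With
    ``enforce_aspect_limit`` (the family's historical behaviour) boxes whose
    aspect ratio ``max(w/h, h/w)`` reaches ``limit`` are removed too;
    disabling the limit keeps elongated root boxes in the training set.
    """
    out = []
    for b in boxes:
        if b.w <= 0 or b.h <= 0:
            continue
        if enforce_aspect_limit and max(b.w / b.h, b.h / b.w) >= limit:
            continue
        out.append(b)
    return out


_KIND_TO_YAML = {
    "conv": "Conv",
    "c2f": "C2f",
    "sppf": "SPPF",
    "upsample": "nn.Upsample",
    "concat": "Concat",
    "segment_head": "Segment",
}
_YAML_TO_KIND = {v: k for k, v in _KIND_TO_YAML.items()}


def export_model_config(spec: ArchitectureSpec) -> str:
    """Serialize a spec to the YOLO-family YAML model-config dialect.

    Channels are emitted as realized values (no scaling on import), so
    ``import_model_config(export_model_config(spec)) == spec``.
    """
    layers = []
    for l in spec.layers:
        entry = {
            "from": list(l.from_),
            "module": _KIND_TO_YAML[l.kind],
            "args": {
                "out_ch": l.out_ch,
                "kernel": l.kernel,
                "stride": l.stride,
                "repeats": l.repeats,
                "shortcut": l.shortcut,
            },
        }
        layers.append(entry)
    doc = {
        "variant": spec.variant,
        "nc": spec.num_classes,
        "depth_multiple": spec.depth_mult,
        "width_multiple": spec.width_mult,
        "max_channels": spec.max_channels,
        "head_strides": list(spec.head_strides),
        "mask_protos": spec.mask_protos,
        "proto_channels": spec.proto_channels,
        "layers": layers,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def import_model_config(text: str) -> ArchitectureSpec:
    """Parse a model-config document back into an :class:`ArchitectureSpec`."""
    doc = yaml.safe_load(text)
    layers = tuple(
        LayerSpec(
            kind=_YAML_TO_KIND[entry["module"]],
            from_=tuple(entry["from"]),
            out_ch=entry["args"]["out_ch"],
            kernel=entry["args"]["kernel"],
            stride=entry["args"]["stride"],
            repeats=entry["args"]["repeats"],
            shortcut=entry["args"]["shortcut"],
        )
        for entry in doc["layers"]
    )
    return ArchitectureSpec(
        variant=doc["variant"],
        depth_mult=doc["depth_multiple"],
        width_mult=doc["width_multiple"],
        max_channels=doc["max_channels"],
        num_classes=doc["nc"],
        layers=layers,
        head_strides=tuple(doc["head_strides"]),
        mask_protos=doc["mask_protos"],
        proto_channels=doc["proto_channels"],
    )
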