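"""Model graph assembly and architecture profiling.

The detector follows the YOLOv8-style layout: a backbone of stride-2
convolutions interleaved with fusion blocks (C2f cross-stage-partial blocks
in the baseline, kernel-team fusion blocks in the KT variant) terminated by
an SPPF layer, a top-down/bottom-up neck, and an anchor-free decoupled head
with 16-bin distribution-based box regression on three pyramid levels at
strides 8/16/32.  At a 640x640 input the pyramid features are 64x80x80,
128x40x40 and 256x20x20 at nano widths.

``profile`` counts parameters and floating-point operations symbolically
(convolution FLOPs = 2 x k^2 x Cin x Cout x Hout x Wout, i.e. two ops per
multiply-accumulate, plus bias adds; upsampling/concat/pooling count zero),
the convention under which the stock nano baseline totals 8.7 GFLOPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ktf import KernelTeamConfig, KTFBlock, partition_channels
from .nn import Concat, Conv2d, ConvBN, MaxPool2d, Module, Upsample2x

__all__ = [
    "LayerSpec",
    "ModelGraph",
    "ModelConfig",
    "ProfileReport",
    "build_backbone",
    "build_detector",
    "profile",
    "C2f",
    "SPPF",
    "DetectHead",
    "GraphNet",
    "build_network",
]

LAYER_KINDS = {"input", "conv", "c2f", "ktf", "sppf", "upsample", "concat", "detect_head"}


@dataclass
class ModelConfig:
    """Widths/depths and block choices of the detector.

    ``widths`` are the five stage widths (stem through deepest stage);
    ``depths`` the bottleneck repeat counts of the four backbone fusion
    blocks.  ``fusion`` selects C2f (baseline) or KTF blocks for backbone
    stages 2-4 and the neck.  Defaults are the nano scale.
    """

    num_classes: int = 80
    widths: tuple = (16, 32, 64, 128, 256)
    depths: tuple = (1, 2, 2, 1)
    fusion: str = "c2f"  # "c2f" | "ktf"
    kernel_sizes: tuple = (1, 3, 5, 7)
    min_channels_per_group: int = 8
    work_fraction: float = 0.5
    reg_max: int = 16

    def __post_init__(self):
        if self.fusion not in ("c2f", "ktf"):
            raise ValueError(f"fusion must be 'c2f' or 'ktf', got {self.fusion!r}")
        if len(self.widths) != 5 or any(w < 2 for w in self.widths):
            raise ValueError("widths must be five integers >= 2")
        if len(self.depths) != 4 or any(d < 1 for d in self.depths):
            raise ValueError("depths must be four positive integers")
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown model config keys: {sorted(extra)}")
        d = dict(d)
        for key in ("widths", "depths", "kernel_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class LayerSpec:
    kind: str
    sources: list  # indices of producer layers; -1 is the network input
    in_channels: int = 0
    out_channels: int = 0
    stride: int = 1
    kernel: int = 1
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass
class ModelGraph:
    layers: list
    config: ModelConfig
    pyramid: tuple = ()  # indices of the three head-input layers
    head_strides: tuple = (8, 16, 32)
    input_size: tuple = (640, 640)

    def __post_init__(self):
        for i, layer in enumerate(self.layers):
            for s in layer.sources:
                if s >= i:
                    raise ValueError(f"layer {i} sources must precede it (got {s})")

    def shapes(self, input_size=None) -> list:
        """Symbolic (C, H, W) output shape of every layer."""
        h, w = input_size or self.input_size
        out: list = []
        for layer in self.layers:
            srcs = [(3, h, w) if s == -1 else out[s] for s in layer.sources]
            if layer.kind == "conv":
                c0, h0, w0 = srcs[0]
                if layer.stride > 1 and (h0 % layer.stride or w0 % layer.stride):
                    raise ValueError(
                        f"stride-{layer.stride} conv on odd spatial size {h0}x{w0}"
                    )
                out.append((layer.out_channels, h0 // layer.stride, w0 // layer.stride))
            elif layer.kind in ("c2f", "ktf", "sppf"):
                c0, h0, w0 = srcs[0]
                out.append((layer.out_channels, h0, w0))
            elif layer.kind == "upsample":
                c0, h0, w0 = srcs[0]
                out.append((c0, h0 * 2, w0 * 2))
            elif layer.kind == "concat":
                hs = {(s[1], s[2]) for s in srcs}
                if len(hs) != 1:
                    raise ValueError(f"concat over mismatched spatial sizes {hs}")
                out.append((sum(s[0] for s in srcs), srcs[0][1], srcs[0][2]))
            elif layer.kind == "detect_head":
                out.append(srcs[0])  # placeholder; head outputs handled separately
            else:
                raise ValueError(layer.kind)
        return out


def _fusion_layer(cfg: ModelConfig, src: int, cin: int, cout: int, n: int,
                  shortcut: bool, force_c2f: bool = False) -> LayerSpec:
    if cfg.fusion == "ktf" and not force_c2f:
        return LayerSpec("ktf", [src], cin, cout, extra={
            "kernel_sizes": cfg.kernel_sizes,
            "min_channels_per_group": cfg.min_channels_per_group,
            "work_fraction": cfg.work_fraction,
        })
    return LayerSpec("c2f", [src], cin, cout, extra={"n": n, "shortcut": shortcut})


def build_backbone(config: ModelConfig) -> ModelGraph:
    """Backbone: stem, four stride-2 stages with fusion blocks, SPPF.

    Stage 1's fusion block stays C2f in both variants; stages 2-4 use the
    configured fusion kind.  Pyramid outputs are the stage-2 and stage-3
    fusion blocks and the SPPF (strides 8/16/32).
    """
    w0, w1, w2, w3, w4 = config.widths
    d = config.depths
    layers = [
        LayerSpec("conv", [-1], 3, w0, stride=2, kernel=3),                 # 0
        LayerSpec("conv", [0], w0, w1, stride=2, kernel=3),                 # 1
        _fusion_layer(config, 1, w1, w1, d[0], True, force_c2f=True),       # 2
        LayerSpec("conv", [2], w1, w2, stride=2, kernel=3),                 # 3
        _fusion_layer(config, 3, w2, w2, d[1], True),                       # 4  P3
        LayerSpec("conv", [4], w2, w3, stride=2, kernel=3),                 # 5
        _fusion_layer(config, 5, w3, w3, d[2], True),                       # 6  P4
        LayerSpec("conv", [6], w3, w4, stride=2, kernel=3),                 # 7
        _fusion_layer(config, 7, w4, w4, d[3], True),                       # 8
        LayerSpec("sppf", [8], w4, w4, kernel=5),                           # 9  P5
    ]
    return ModelGraph(layers, config, pyramid=(4, 6, 9))


def build_detector(config: ModelConfig) -> ModelGraph:
    """Full detector: backbone + top-down/bottom-up neck + decoupled head."""
    graph = build_backbone(config)
    w0, w1, w2, w3, w4 = config.widths
    layers = list(graph.layers)
    layers += [
        LayerSpec("upsample", [9]),                                         # 10
        LayerSpec("concat", [10, 6]),                                       # 11
        _fusion_layer(config, 11, w4 + w3, w3, 1, False),                   # 12
        LayerSpec("upsample", [12]),                                        # 13
        LayerSpec("concat", [13, 4]),                                       # 14
        _fusion_layer(config, 14, w3 + w2, w2, 1, False),                   # 15 head P3
        LayerSpec("conv", [15], w2, w2, stride=2, kernel=3),                # 16
        LayerSpec("concat", [16, 12]),                                      # 17
        _fusion_layer(config, 17, w2 + w3, w3, 1, False),                   # 18 head P4
        LayerSpec("conv", [18], w3, w3, stride=2, kernel=3),                # 19
        LayerSpec("concat", [19, 9]),                                       # 20
        _fusion_layer(config, 20, w3 + w4, w4, 1, False),                   # 21 head P5
        LayerSpec("detect_head", [15, 18, 21], extra={
            "num_classes": config.num_classes, "reg_max": config.reg_max,
        }),                                                                 # 22
    ]
    return ModelGraph(layers, config, pyramid=(15, 18, 21))


# ---------------------------------------------------------------------------
# profiling

@dataclass
class ConvAtom:
    k: int
    cin: int
    cout: int
    hout: int
    wout: int
    bias: bool
    bn: bool

    @property
    def flops(self) -> int:
        f = 2 * self.k * self.k * self.cin * self.cout * self.hout * self.wout
        if self.bias:
            f += self.cout * self.hout * self.wout
        return f

    @property
    def params(self) -> int:
        p = self.k * self.k * self.cin * self.cout
        if self.bias:
            p += self.cout
        if self.bn:
            p += 2 * self.cout
        return p


@dataclass
class ProfileReport:
    total_params: int
    total_flops: int
    input_size: tuple
    per_layer: list  # (layer index, kind, params, flops)

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.per_layer, columns=["layer", "kind", "params", "flops"])
        return df


def _c2f_atoms(cin, cout, n, h, w):
    c = cout // 2
    atoms = [ConvAtom(1, cin, 2 * c, h, w, False, True)]
    for _ in range(n):
        atoms += [ConvAtom(3, c, c, h, w, False, True), ConvAtom(3, c, c, h, w, False, True)]
    atoms.append(ConvAtom(1, (2 + n) * c, cout, h, w, False, True))
    return atoms


def _ktf_atoms(cin, cout, extra, h, w):
    cfg = KernelTeamConfig(
        kernel_sizes=extra["kernel_sizes"],
        min_channels_per_group=extra["min_channels_per_group"],
        work_fraction=extra["work_fraction"],
        out_channels=cout,
    )
    width = max(2, cout)
    wf = cfg.work_fraction
    work_c = width if wf == 1.0 else min(max(int(round(wf * width)), 1), width - 1)
    part = partition_channels(work_c, cfg)
    atoms = [ConvAtom(1, cin, width, h, w, False, True)]
    atoms += [ConvAtom(k, c, c, h, w, False, True)
              for c, k in zip(part.group_channels, part.group_kernels)]
    atoms.append(ConvAtom(1, part.total, work_c, h, w, False, True))  # team 1x1 fusion
    atoms.append(ConvAtom(1, width, cout, h, w, False, True))         # block 1x1 fusion
    return atoms


def _sppf_atoms(cin, cout, h, w):
    c = cin // 2
    return [ConvAtom(1, cin, c, h, w, False, True),
            ConvAtom(1, 4 * c, cout, h, w, False, True)]


def _head_atoms(channels, sizes, num_classes, reg_max):
    c2 = max(16, channels[0] // 4, reg_max * 4)
    c3 = max(channels[0], min(num_classes, 100))
    atoms = []
    for ch, (h, w) in zip(channels, sizes):
        atoms += [
            ConvAtom(3, ch, c2, h, w, False, True),
            ConvAtom(3, c2, c2, h, w, False, True),
            ConvAtom(1, c2, 4 * reg_max, h, w, True, False),
            ConvAtom(3, ch, c3, h, w, False, True),
            ConvAtom(3, c3, c3, h, w, False, True),
            ConvAtom(1, c3, num_classes, h, w, True, False),
        ]
    return atoms


def layer_atoms(graph: ModelGraph, input_size=None) -> list:
    """Per-layer primitive convolution atoms (index-aligned with layers)."""
    shapes = graph.shapes(input_size)
    h_in, w_in = input_size or graph.input_size
    result = []
    for i, layer in enumerate(graph.layers):
        src_shapes = [(3, h_in, w_in) if s == -1 else shapes[s] for s in layer.sources]
        c, h, w = shapes[i]
        if layer.kind == "conv":
            result.append([ConvAtom(layer.kernel, layer.in_channels, layer.out_channels,
                                    h, w, False, True)])
        elif layer.kind == "c2f":
            result.append(_c2f_atoms(layer.in_channels, layer.out_channels,
                                     layer.extra["n"], h, w))
        elif layer.kind == "ktf":
            result.append(_ktf_atoms(layer.in_channels, layer.out_channels, layer.extra, h, w))
        elif layer.kind == "sppf":
            result.append(_sppf_atoms(layer.in_channels, layer.out_channels, h, w))
        elif layer.kind == "detect_head":
            result.append(_head_atoms([s[0] for s in src_shapes],
                                      [(s[1], s[2]) for s in src_shapes],
                                      layer.extra["num_classes"], layer.extra["reg_max"]))
        else:
            result.append([])
    return result


def profile(graph: ModelGraph, input_size=None) -> ProfileReport:
    """Parameter and FLOP totals at ``input_size`` (default the graph's)."""
    atoms = layer_atoms(graph, input_size)
    per_layer = []
    for i, (layer, layer_at) in enumerate(zip(graph.layers, atoms)):
        p = sum(a.params for a in layer_at)
        f = sum(a.flops for a in layer_at)
        per_layer.append((i, layer.kind, p, f))
    total_p = sum(p for _, _, p, _ in per_layer)
    total_f = sum(f for _, _, _, f in per_layer)
    return ProfileReport(total_p, total_f, input_size or graph.input_size, per_layer)


# ---------------------------------------------------------------------------
# runnable modules

class C2f(Module):
    """Cross-stage-partial block with two convolutions and n bottlenecks."""

    def __init__(self, cin, cout, n=1, shortcut=False, rng=None):
        rng = rng or np.random.default_rng(0)
        self.c = cout // 2
        self.cv1 = ConvBN(cin, 2 * self.c, 1, rng=rng)
        self.bottlenecks = [
            (ConvBN(self.c, self.c, 3, rng=rng), ConvBN(self.c, self.c, 3, rng=rng))
            for _ in range(n)
        ]
        self.cv2 = ConvBN((2 + n) * self.c, cout, 1, rng=rng)
        self.shortcut = shortcut
        self.n = n

    def forward(self, x, train: bool = False):
        y = self.cv1(x, train=train)
        ys = [y[:, : self.c], y[:, self.c :]]
        for a, b in self.bottlenecks:
            z = b(a(ys[-1], train=train), train=train)
            ys.append(ys[-1] + z if self.shortcut else z)
        self._concat = Concat()
        return self.cv2(self._concat(*ys, train=train), train=train)

    def backward(self, dy):
        dparts = self._concat.backward(self.cv2.backward(dy))
        # walk the bottleneck chain backwards, accumulating into its input
        grads = list(dparts)
        for i in range(len(self.bottlenecks), 0, -1):
            a, b = self.bottlenecks[i - 1]
            d = grads[i + 1]
            dx = a.backward(b.backward(d))
            if self.shortcut:
                dx = dx + d
            grads[i] = grads[i] + dx
        dcv1 = np.concatenate([grads[0], grads[1]], axis=1)
        return self.cv1.backward(dcv1)


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained stride-1 max pools."""

    def __init__(self, cin, cout, k=5, rng=None):
        rng = rng or np.random.default_rng(0)
        c = cin // 2
        self.cv1 = ConvBN(cin, c, 1, rng=rng)
        self.pools = [MaxPool2d(k), MaxPool2d(k), MaxPool2d(k)]
        self.cv2 = ConvBN(4 * c, cout, 1, rng=rng)

    def forward(self, x, train: bool = False):
        y = self.cv1(x, train=train)
        p1 = self.pools[0](y, train=train)
        p2 = self.pools[1](p1, train=train)
        p3 = self.pools[2](p2, train=train)
        self._concat = Concat()
        return self.cv2(self._concat(y, p1, p2, p3, train=train), train=train)

    def backward(self, dy):
        dy0, dp1, dp2, dp3 = self._concat.backward(self.cv2.backward(dy))
        dp2 = dp2 + self.pools[2].backward(dp3)
        dp1 = dp1 + self.pools[1].backward(dp2)
        dy0 = dy0 + self.pools[0].backward(dp1)
        return self.cv1.backward(dy0)


class DetectHead(Module):
    """Anchor-free decoupled head: per level a box branch emitting 4 x reg_max
    distribution logits and a classification branch emitting class logits."""

    def __init__(self, channels, num_classes, reg_max=16, rng=None):
        rng = rng or np.random.default_rng(0)
        c2 = max(16, channels[0] // 4, reg_max * 4)
        c3 = max(channels[0], min(num_classes, 100))
        self.num_classes = num_classes
        self.reg_max = reg_max
        self.box_branches = []
        self.cls_branches = []
        for ch in channels:
            box_out = Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng)
            # bias the initial distance distributions toward small offsets so
            # freshly initialized boxes are compact rather than grid-filling
            box_out.bias.value[:] = np.tile(-0.4 * np.arange(reg_max, dtype=np.float32), 4)
            self.box_branches.append([
                ConvBN(ch, c2, 3, rng=rng),
                ConvBN(c2, c2, 3, rng=rng),
                box_out,
            ])
            cls_out = Conv2d(c3, num_classes, 1, bias=True, rng=rng)
            # rare-positive prior keeps early training stable on dense grids
            cls_out.bias.value[:] = -4.6  # sigmoid ~ 0.01
            self.cls_branches.append([
                ConvBN(ch, c3, 3, rng=rng),
                ConvBN(c3, c3, 3, rng=rng),
                cls_out,
            ])

    def forward(self, feats, train: bool = False):
        outs = []
        for f, bb, cb in zip(feats, self.box_branches, self.cls_branches):
            box = f
            for m in bb:
                box = m(box, train=train)
            cls = f
            for m in cb:
                cls = m(cls, train=train)
            outs.append((box, cls))
        return outs

    def backward(self, douts):
        dfeats = []
        for (dbox, dcls), bb, cb in zip(douts, self.box_branches, self.cls_branches):
            for m in reversed(bb):
                dbox = m.backward(dbox)
            for m in reversed(cb):
                dcls = m.backward(dcls)
            dfeats.append(dbox + dcls)
        return dfeats


class GraphNet(Module):
    """Executes a topologically ordered layer graph with gradient support."""

    def __init__(self, modules, sources, output_indices):
        self.modules = modules
        self.sources = sources
        self.output_indices = tuple(output_indices)

    def forward(self, x, train: bool = False):
        outs = {}
        for i, (m, srcs) in enumerate(zip(self.modules, self.sources)):
            inputs = [x if s == -1 else outs[s] for s in srcs]
            outs[i] = m(*inputs, train=train)
        self._n = len(self.modules)
        return [outs[i] for i in self.output_indices]

    def backward(self, doutputs):
        grads: dict = {}
        for idx, g in zip(self.output_indices, doutputs):
            grads[idx] = grads.get(idx, 0) + g
        dinput = None
        for i in range(self._n - 1, -1, -1):
            g = grads.pop(i, None)
            if g is None:
                continue
            src_grads = self.modules[i].backward(g)
            if not isinstance(src_grads, (list, tuple)):
                src_grads = [src_grads]
            for s, sg in zip(self.sources[i], src_grads):
                if s == -1:
                    dinput = sg if dinput is None else dinput + sg
                else:
                    grads[s] = grads[s] + sg if s in grads else sg
        return dinput


def build_network(graph: ModelGraph, rng: np.random.Generator | None = None):
    """Instantiate the runnable numpy network for a detector graph.

    Returns ``(net, head)`` where ``net`` maps an image batch to the three
    pyramid features and ``head`` is the decoupled detection head (or None
    for a bare backbone graph).
    """
    rng = rng or np.random.default_rng(0)
    modules, sources = [], []
    head = None
    shapes = graph.shapes()
    for i, layer in enumerate(graph.layers):
        if layer.kind == "conv":
            m = ConvBN(layer.in_channels, layer.out_channels, layer.kernel, layer.stride, rng=rng)
        elif layer.kind == "c2f":
            m = C2f(layer.in_channels, layer.out_channels, layer.extra["n"],
                    layer.extra["shortcut"], rng=rng)
        elif layer.kind == "ktf":
            cfg = KernelTeamConfig(
                kernel_sizes=layer.extra["kernel_sizes"],
                min_channels_per_group=layer.extra["min_channels_per_group"],
                work_fraction=layer.extra["work_fraction"],
                out_channels=layer.out_channels,
            )
            m = KTFBlock(layer.in_channels, cfg, rng=rng)
        elif layer.kind == "sppf":
            m = SPPF(layer.in_channels, layer.out_channels, layer.kernel, rng=rng)
        elif layer.kind == "upsample":
            m = Upsample2x()
        elif layer.kind == "concat":
            m = Concat()
        elif layer.kind == "detect_head":
            head = DetectHead([shapes[s][0] for s in layer.sources],
                              layer.extra["num_classes"], layer.extra["reg_max"], rng=rng)
            continue
        else:
            raise ValueError(layer.kind)
        modules.append(m)
        sources.append(list(layer.sources))
    net = GraphNet(modules, sources, graph.pyramid)
    return net, head
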