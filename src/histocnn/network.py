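"""Two-branch CNN architecture: inception stack with per-module SE gates.

The same network is instantiated twice at runtime — once as the global branch
(whole downsampled image) and once as the local branch (patches) — so this
module only builds a single branch.  It also exposes the squeeze / excite /
scale computations as standalone functions operating on (H, W, C) grids, a
parameter/FLOP counter, and the structural channel-surgery entry points used
by the pruning stage.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

from . import nn
from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    SEBlock,
    Sequential,
    se_bottleneck_width,
    softmax,
)

INCEPTION_NAMES = ("3a", "3b", "4a", "4b", "4c", "4d", "4e")

#: Output channel totals per inception module at width multiplier 1.
INCEPTION_TOTALS = {"3a": 256, "3b": 480, "4a": 512, "4b": 512,
                    "4c": 512, "4d": 528, "4e": 1856}


class ArchitectureError(ValueError):
    """Raised when an architecture spec violates its structural invariants."""


def load_inception_widths() -> dict[str, dict[str, int]]:
    """Load the committed per-branch width allocation table."""
    text = resources.files("histocnn.resources").joinpath("inception_widths.yaml").read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Squeeze / excite / scale as standalone grid operations
# ---------------------------------------------------------------------------

@dataclass
class SEPBlockParams:
    """Weights of the two bias-free FC layers of an SE gate.

    ``w1`` has shape (bottleneck, C) and ``w2`` shape (C, bottleneck) with
    bottleneck = max(1, round(C / r)).
    """

    w1: np.ndarray
    w2: np.ndarray
    reduction: int = 16

    def __post_init__(self):
        self.w1 = np.atleast_2d(np.asarray(self.w1, dtype=float))
        self.w2 = np.atleast_2d(np.asarray(self.w2, dtype=float))
        if self.w1.shape[0] != self.w2.shape[1] or self.w1.shape[1] != self.w2.shape[0]:
            raise ValueError(
                f"inconsistent FC shapes {self.w1.shape} / {self.w2.shape}"
            )

    @property
    def channels(self) -> int:
        return self.w1.shape[1]


def se_squeeze(x: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of an (H, W, C) activation grid."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or min(x.shape) < 1:
        raise ValueError("expected a non-empty (H, W, C) grid")
    if not np.all(np.isfinite(x)):
        raise ValueError("activations must be finite")
    return x.mean(axis=(0, 1))


def se_excite(z: np.ndarray, params: SEPBlockParams) -> np.ndarray:
    """Activation factors s = sigmoid(W2 @ relu(W1 @ z)); values in (0, 1)."""
    z = np.asarray(z, dtype=float).ravel()
    if z.shape[0] != params.channels:
        raise ValueError(f"z has {z.shape[0]} channels, params expect {params.channels}")
    h = np.maximum(params.w1 @ z, 0.0)
    return 1.0 / (1.0 + np.exp(-(params.w2 @ h)))


def se_scale(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Reweight each channel of an (H, W, C) grid by its activation factor."""
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float).ravel()
    if x.ndim != 3 or x.shape[2] != s.shape[0]:
        raise ValueError("channel count of x must match length of s")
    return x * s[None, None, :]


# ---------------------------------------------------------------------------
# Architecture spec
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Structural description of one branch network.

    ``width_multiplier`` scales every channel count (floor of 1) to produce
    desk-scale models; at multiplier 1 the module output widths match the
    reference layer table (256, 480, 512, 512, 512, 528, 1856).
    """

    width_multiplier: float = 1.0
    input_side: int = 224
    n_classes: int = 2
    reduction: int = 16
    stem_channels: tuple[int, int, int] = (64, 64, 192)
    inception_widths: dict[str, dict[str, int]] = field(default_factory=load_inception_widths)
    # (source SE output, insertion point) pairs; fixed concrete reading.
    residual_links: tuple[tuple[str, str], ...] = (("4c", "4e_in"), ("4d", "4e_out"))

    def scaled(self, c: int) -> int:
        return max(1, int(np.floor(c * self.width_multiplier + 0.5)))

    def validate(self) -> None:
        if tuple(self.inception_widths) != INCEPTION_NAMES:
            raise ArchitectureError(
                f"expected exactly 7 inception modules {INCEPTION_NAMES}, "
                f"got {tuple(self.inception_widths)}"
            )
        if self.n_classes != 2:
            raise ArchitectureError("output class count must be 2")
        if not (0 < self.width_multiplier <= 1):
            raise ArchitectureError("width_multiplier must lie in (0, 1]")
        for name, w in self.inception_widths.items():
            total = w["n1"] + w["n3"] + w["n5"] + w["pool"]
            if total != w["total"]:
                raise ArchitectureError(
                    f"inception {name}: branch widths sum to {total}, "
                    f"declared total is {w['total']}"
                )

    def module_out_channels(self, name: str) -> int:
        w = self.inception_widths[name]
        return sum(self.scaled(w[k]) for k in ("n1", "n3", "n5", "pool"))

    def to_yaml(self) -> str:
        payload = {
            "width_multiplier": self.width_multiplier,
            "input_side": self.input_side,
            "n_classes": self.n_classes,
            "reduction": self.reduction,
            "stem_channels": list(self.stem_channels),
            "inception_widths": self.inception_widths,
            "residual_links": [list(p) for p in self.residual_links],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        d = yaml.safe_load(text)
        d["stem_channels"] = tuple(d["stem_channels"])
        d["residual_links"] = tuple(tuple(p) for p in d["residual_links"])
        return cls(**d)

    @classmethod
    def toy(cls, width_multiplier: float = 0.125, input_side: int = 64) -> "ArchitectureSpec":
        """Desk-scale test profile: 1/8 widths, 64-px inputs."""
        return cls(width_multiplier=width_multiplier, input_side=input_side)


# ---------------------------------------------------------------------------
# Inception module
# ---------------------------------------------------------------------------

_BRANCH_ORDER = ("b1", "b2", "b3", "b4")


def _conv_bn_relu(cin, cout, k, pad, rng, stride=1):
    return [Conv2d(cin, cout, k, stride=stride, padding=pad, bias=False, rng=rng),
            BatchNorm2d(cout), ReLU()]


class InceptionModule(Module):
    """Four parallel branches concatenated channel-wise.

    b1: 1x1 conv; b2: 1x1 reduce -> 3x3; b3: 1x1 reduce -> 5x5;
    b4: 3x3 max pool (stride 1) -> 1x1 projection.  Branches whose output
    width has been pruned to zero are dropped structurally (``None``).
    """

    def __init__(self, in_channels: int, widths: Mapping[str, int],
                 rng: np.random.Generator):
        self.branches: dict[str, Sequential | None] = {
            "b1": Sequential(_conv_bn_relu(in_channels, widths["n1"], 1, 0, rng)),
            "b2": Sequential(_conv_bn_relu(in_channels, widths["n3r"], 1, 0, rng)
                             + _conv_bn_relu(widths["n3r"], widths["n3"], 3, 1, rng)),
            "b3": Sequential(_conv_bn_relu(in_channels, widths["n5r"], 1, 0, rng)
                             + _conv_bn_relu(widths["n5r"], widths["n5"], 5, 2, rng)),
            "b4": Sequential([MaxPool2d(3, 1, 1)]
                             + _conv_bn_relu(in_channels, widths["pool"], 1, 0, rng)),
        }
        self.out_widths = {"b1": widths["n1"], "b2": widths["n3"],
                           "b3": widths["n5"], "b4": widths["pool"]}

    @property
    def out_channels(self) -> int:
        return sum(self.out_widths.values())

    def _entry_convs(self) -> list[Conv2d]:
        convs = []
        for name in _BRANCH_ORDER:
            br = self.branches[name]
            if br is None:
                continue
            first = br.layers[1] if name == "b4" else br.layers[0]
            convs.append(first)
        return convs

    def _final_conv_bn(self, name: str) -> tuple[Conv2d, BatchNorm2d]:
        br = self.branches[name]
        if name == "b1":
            return br.layers[0], br.layers[1]
        if name == "b4":
            return br.layers[1], br.layers[2]
        return br.layers[3], br.layers[4]  # b2 / b3: second conv

    def forward(self, x, train=True):
        outs = []
        for name in _BRANCH_ORDER:
            br = self.branches[name]
            if br is not None:
                outs.append(br.forward(x, train=train))
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        dx = None
        start = 0
        for name in _BRANCH_ORDER:
            br = self.branches[name]
            if br is None:
                continue
            w = self.out_widths[name]
            g = grad[:, start : start + w]
            start += w
            d = br.backward(g)
            dx = d if dx is None else dx + d
        return dx

    def parameters(self):
        for name in _BRANCH_ORDER:
            if self.branches[name] is not None:
                yield from self.branches[name].parameters()

    def children(self):
        return iter(br for br in self.branches.values() if br is not None)

    # -- surgery -----------------------------------------------------------
    def slice_output(self, kept: np.ndarray) -> None:
        """Keep only the given concatenated output channels.

        Indices are mapped through the concatenation order back to the owning
        branch's final convolution; a branch losing every channel is dropped.
        """
        kept = np.asarray(kept)
        start = 0
        for name in _BRANCH_ORDER:
            if self.branches[name] is None:
                continue
            w = self.out_widths[name]
            local = kept[(kept >= start) & (kept < start + w)] - start
            start += w
            if local.size == 0:
                self.branches[name] = None
                self.out_widths[name] = 0
                continue
            conv, bn = self._final_conv_bn(name)
            conv.slice_out(local)
            bn.slice(local)
            self.out_widths[name] = local.size

    def slice_input(self, kept: np.ndarray) -> None:
        for conv in self._entry_convs():
            conv.slice_in(kept)


# ---------------------------------------------------------------------------
# Branch network
# ---------------------------------------------------------------------------

class HybridBranchNet(Module):
    """One branch: stem -> 7 inception+SE stages with residual links -> head."""

    def __init__(self, arch: ArchitectureSpec, seed: int = 0):
        arch.validate()
        self.arch = arch
        rng = np.random.default_rng(seed)
        s1, s2, s3 = (arch.scaled(c) for c in arch.stem_channels)
        self.stem = Sequential(
            _conv_bn_relu(3, s1, 7, 3, rng, stride=2)
            + [MaxPool2d(3, 2, 1)]
            + _conv_bn_relu(s1, s2, 1, 0, rng)
            + _conv_bn_relu(s2, s3, 3, 1, rng)
            + [MaxPool2d(3, 2, 1)]
        )
        self.inception: dict[str, InceptionModule] = {}
        self.sep: dict[str, SEBlock] = {}
        cin = s3
        for name in INCEPTION_NAMES:
            widths = {k: arch.scaled(v) for k, v in arch.inception_widths[name].items()
                      if k != "total"}
            mod = InceptionModule(cin, widths, rng)
            self.inception[name] = mod
            self.sep[name] = SEBlock(mod.out_channels, arch.reduction, rng=rng)
            cin = mod.out_channels
        self.pool3 = MaxPool2d(3, 2, 1)
        self.pool4 = MaxPool2d(3, 2, 1)
        c4c = self.inception["4c"].out_channels
        c4d = self.inception["4d"].out_channels
        c4e = self.inception["4e"].out_channels
        # 1x1 projection shortcuts; identity when channel counts agree.
        self.proj_c = (Conv2d(c4c, c4d, 1, rng=rng) if c4c != c4d else None)
        self.proj_d = (Conv2d(c4d, c4e, 1, rng=rng) if c4d != c4e else None)
        self.gap = GlobalAvgPool()
        self.fc = Linear(c4e, arch.n_classes, rng=rng)
        self._cache = None

    # -- forward / backward ------------------------------------------------
    def _stage(self, name: str, x, train):
        return self.sep[name].forward(self.inception[name].forward(x, train), train)

    def _stage_backward(self, name: str, g):
        return self.inception[name].backward(self.sep[name].backward(g))

    def forward(self, x, train=True, return_logits=False):
        x = self.stem.forward(x, train)
        for name in ("3a", "3b"):
            x = self._stage(name, x, train)
        x = self.pool3.forward(x, train)
        for name in ("4a", "4b"):
            x = self._stage(name, x, train)
        t_c = self._stage("4c", x, train)
        t_d = self._stage("4d", t_c, train)
        x4e_in = t_d + (self.proj_c.forward(t_c, train) if self.proj_c else t_c)
        t_e = self._stage("4e", x4e_in, train)
        t = t_e + (self.proj_d.forward(t_d, train) if self.proj_d else t_d)
        h = self.pool4.forward(t, train)
        h = self.gap.forward(h, train)
        logits = self.fc.forward(h, train)
        return logits if return_logits else softmax(logits)

    def backward(self, grad_logits):
        g = self.fc.backward(grad_logits)
        g = self.gap.backward(g)
        dt = self.pool4.backward(g)
        # t = t_e + proj_d(t_d)
        dt_e = dt
        dt_d = self.proj_d.backward(dt) if self.proj_d else dt.copy()
        dx4e_in = self._stage_backward("4e", dt_e)
        # x4e_in = t_d + proj_c(t_c)
        dt_d = dt_d + dx4e_in
        dt_c_res = self.proj_c.backward(dx4e_in) if self.proj_c else dx4e_in
        dt_c = self._stage_backward("4d", dt_d) + dt_c_res
        g = self._stage_backward("4c", dt_c)
        for name in ("4b", "4a"):
            g = self._stage_backward(name, g)
        g = self.pool3.backward(g)
        for name in ("3b", "3a"):
            g = self._stage_backward(name, g)
        return self.stem.backward(g)

    def parameters(self):
        yield from self.stem.parameters()
        for name in INCEPTION_NAMES:
            yield from self.inception[name].parameters()
            yield from self.sep[name].parameters()
        for proj in (self.proj_c, self.proj_d):
            if proj is not None:
                yield from proj.parameters()
        yield from self.fc.parameters()

    def children(self):
        yield self.stem
        for name in INCEPTION_NAMES:
            yield self.inception[name]
            yield self.sep[name]
        for proj in (self.proj_c, self.proj_d):
            if proj is not None:
                yield proj
        yield self.fc

    # -- pruning interface -------------------------------------------------
    def se_layers(self) -> dict[str, SEBlock]:
        return dict(self.sep)

    @property
    def prunable_layers(self) -> tuple[str, ...]:
        return INCEPTION_NAMES

    def residual_coupled_pairs(self) -> list[tuple[str, str]]:
        """Layer pairs added through identity shortcuts (must share masks)."""
        pairs = []
        if self.proj_c is None:
            pairs.append(("4c", "4d"))
        if self.proj_d is None:
            pairs.append(("4d", "4e"))
        return pairs

    def prune(self, masks: Mapping[str, np.ndarray]) -> None:
        """Physically remove inception output channels per layer mask.

        ``masks`` maps layer name -> strictly increasing kept-channel indices.
        The stem is never prunable.
        """
        for name in masks:
            if name not in INCEPTION_NAMES:
                raise ValueError(f"layer {name!r} is not prunable")
        for a, b in self.residual_coupled_pairs():
            if (a in masks) != (b in masks) or (
                a in masks and not np.array_equal(masks[a], masks[b])
            ):
                raise ValueError(f"residual-coupled layers {a}/{b} need a shared mask")
        order = list(INCEPTION_NAMES)
        consumers = {name: order[i + 1] if i + 1 < len(order) else None
                     for i, name in enumerate(order)}
        for name, kept in masks.items():
            kept = np.asarray(kept, dtype=int)
            c = self.inception[name].out_channels
            if kept.size < 1 or kept.size > c or np.any(np.diff(kept) <= 0):
                raise ValueError(f"invalid mask for layer {name}")
            if kept.min() < 0 or kept.max() >= c:
                raise ValueError(f"mask indices out of range for layer {name}")
            self.inception[name].slice_output(kept)
            self.sep[name].slice(kept)
            nxt = consumers[name]
            if nxt is not None:
                self.inception[nxt].slice_input(kept)
            if name == "4c" and self.proj_c is not None:
                self.proj_c.slice_in(kept)
            if name == "4d":
                if self.proj_c is not None:
                    self.proj_c.slice_out(kept)
                if self.proj_d is not None:
                    self.proj_d.slice_in(kept)
            if name == "4e":
                if self.proj_d is not None:
                    self.proj_d.slice_out(kept)
                self.fc.slice_in(kept)

    # -- bookkeeping -------------------------------------------------------
    def layer_channels(self) -> dict[str, int]:
        return {name: self.inception[name].out_channels for name in INCEPTION_NAMES}

    def shape_manifest(self) -> list[tuple[str, tuple[int, int, int]]]:
        """Analytic per-stage output shapes (H, W, C) for the current model."""

        def conv_out(side, k, s, p):
            return (side + 2 * p - k) // s + 1

        side = self.arch.input_side
        shapes: list[tuple[str, tuple[int, int, int]]] = []
        s1 = self.stem.layers[0].out_channels
        side = conv_out(side, 7, 2, 3)
        shapes.append(("conv7x7/2", (side, side, s1)))
        side = conv_out(side, 3, 2, 1)
        shapes.append(("maxpool3x3/2", (side, side, s1)))
        s2 = self.stem.layers[4].out_channels
        shapes.append(("conv1x1/1", (side, side, s2)))
        s3 = self.stem.layers[7].out_channels
        shapes.append(("conv3x3/1", (side, side, s3)))
        side = conv_out(side, 3, 2, 1)
        shapes.append(("maxpool3x3/2b", (side, side, s3)))
        for name in INCEPTION_NAMES:
            c = self.inception[name].out_channels
            shapes.append((f"inception{name}", (side, side, c)))
            shapes.append((f"sep{name}", (side, side, c)))
            if name == "3b":
                side = conv_out(side, 3, 2, 1)
                shapes.append(("maxpool3x3/2c", (side, side, c)))
        side = conv_out(side, 3, 2, 1)
        c = self.inception["4e"].out_channels
        shapes.append(("maxpool3x3/2d", (side, side, c)))
        shapes.append(("avgpool", (1, 1, c)))
        shapes.append(("linear", (1, 1, self.fc.out_features)))
        return shapes


def build_model(arch: ArchitectureSpec, seed: int = 0) -> HybridBranchNet:
    """Construct one branch network from a validated architecture spec."""
    return HybridBranchNet(arch, seed=seed)


# ---------------------------------------------------------------------------
# Small SE net for unit-scale pruning experiments
# ---------------------------------------------------------------------------

class SmallSENet(Module):
    """Two conv+BN+ReLU+SE stages, global pool, linear head.

    Used as the unit-test workhorse for pruning surgery; implements the same
    ``se_layers`` / ``prune`` interface as :class:`HybridBranchNet`.
    """

    def __init__(self, c1: int = 8, c2: int = 8, n_classes: int = 2,
                 reduction: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(3, c1, 3, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(c1)
        self.relu1 = ReLU()
        self.se1 = SEBlock(c1, reduction, rng=rng)
        self.conv2 = Conv2d(c1, c2, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(c2)
        self.relu2 = ReLU()
        self.se2 = SEBlock(c2, reduction, rng=rng)
        self.gap = GlobalAvgPool()
        self.fc = Linear(c2, n_classes, rng=rng)

    def forward(self, x, train=True, return_logits=False):
        x = self.se1.forward(self.relu1.forward(self.bn1.forward(
            self.conv1.forward(x, train), train), train), train)
        x = self.se2.forward(self.relu2.forward(self.bn2.forward(
            self.conv2.forward(x, train), train), train), train)
        logits = self.fc.forward(self.gap.forward(x, train), train)
        return logits if return_logits else softmax(logits)

    def backward(self, grad_logits):
        g = self.gap.backward(self.fc.backward(grad_logits))
        g = self.conv2.backward(self.bn2.backward(self.relu2.backward(
            self.se2.backward(g))))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.se1.backward(g))))

    def parameters(self):
        for m in (self.conv1, self.bn1, self.se1, self.conv2, self.bn2,
                  self.se2, self.fc):
            yield from m.parameters()

    def children(self):
        return iter((self.conv1, self.bn1, self.se1, self.conv2, self.bn2,
                     self.se2, self.fc))

    def se_layers(self) -> dict[str, SEBlock]:
        return {"conv1": self.se1, "conv2": self.se2}

    @property
    def prunable_layers(self) -> tuple[str, ...]:
        return ("conv1", "conv2")

    def residual_coupled_pairs(self):
        return []

    def layer_channels(self) -> dict[str, int]:
        return {"conv1": self.conv1.out_channels, "conv2": self.conv2.out_channels}

    def prune(self, masks: Mapping[str, np.ndarray]) -> None:
        for name in masks:
            if name not in self.prunable_layers:
                raise ValueError(f"layer {name!r} is not prunable")
        if "conv1" in masks:
            kept = np.asarray(masks["conv1"], dtype=int)
            self.conv1.slice_out(kept)
            self.bn1.slice(kept)
            self.se1.slice(kept)
            self.conv2.slice_in(kept)
        if "conv2" in masks:
            kept = np.asarray(masks["conv2"], dtype=int)
            self.conv2.slice_out(kept)
            self.bn2.slice(kept)
            self.se2.slice(kept)
            self.fc.slice_in(kept)


# ---------------------------------------------------------------------------
# Parameter / FLOP counting
# ---------------------------------------------------------------------------

def count_params_flops(model: Module, input_side: int, in_channels: int = 3
                       ) -> tuple[int, int]:
    """Count trainable scalars and forward FLOPs at the given input size.

    FLOPs are 2 x multiply-accumulates of convolution and fully-connected
    layers (the SE gate's FC pair included); normalization, pooling and
    activations are not counted.
    """
    weights = sum(p.size for p in model.parameters())
    if weights == 0 and not list(model.modules())[1:]:
        return 0, 0
    x = np.zeros((1, in_channels, input_side, input_side))
    for m in model.modules():
        if isinstance(m, (Conv2d, Linear, SEBlock)):
            m.last_macs = 0
    model.forward(x, train=False)
    macs = sum(m.last_macs for m in model.modules()
               if isinstance(m, (Conv2d, Linear, SEBlock)))
    return weights, 2 * macs


def save_model(model: Module, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> Module:
    with open(path, "rb") as fh:
        return pickle.load(fh)
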