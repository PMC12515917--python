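"""DenseNet121 with Selective-Kernel (SK) attention, plus focal loss.

The backbone is the standard densely connected network: four dense
blocks of (6, 12, 24, 16) bottleneck layers with growth rate K = 32,
1x1-conv + average-pool transitions at 0.5 compression, and a BN-ReLU-GAP
classifier head. The reference 1000-class configuration counts 7,978,856
trainable parameters.

The SK module is a dual-branch convolution with a learned per-channel
softmax gate: a 3x3 branch and a 3x3 dilation-2 branch (5x5 receptive
field) are fused by summation, pooled to a channel statistic s, squeezed
to d = max(C/r, L) dimensions, and re-expanded into two gate logits whose
softmax mixes the branches channel by channel (a_c + b_c = 1). One SK
module follows each dense layer, acting on that layer's K-channel output
before concatenation; with grouped (groups=8) branch convolutions the SK
modules add 322,944 parameters (8,301,800 total at the reference head).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    AvgPool2d,
    BatchNorm,
    Conv2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
)
from .nn import core as F

__all__ = [
    "ModelConfig",
    "SKConfig",
    "SKModule",
    "DenseLayer",
    "DenseBlock",
    "Transition",
    "DenseNetSK",
    "build_model",
    "dense_block_forward",
    "sk_reduced_dim",
    "focal_loss",
]


@dataclass(frozen=True)
class ModelConfig:
    growth_rate: int = 32
    block_layout: tuple[int, ...] = (6, 12, 24, 16)
    num_classes: int = 2
    input_size: int = 224
    in_channels: int = 3
    bn_size: int = 4          # bottleneck width multiplier (1x1 conv to bn_size*K)
    compression: float = 0.5  # transition channel compression

    def __post_init__(self):
        if self.growth_rate <= 0:
            raise ValueError("growth rate K must be positive")
        if not self.block_layout:
            raise ValueError("block_layout must be non-empty")


@dataclass(frozen=True)
class SKConfig:
    reduction_ratio: int = 16
    dim_floor: int = 32
    conv_groups: int = 8
    branch_dilations: tuple[int, int] = (1, 2)
    insertion: str = "per_dense_layer"  # or "per_block", "none"

    def __post_init__(self):
        if self.reduction_ratio < 1 or self.dim_floor < 1:
            raise ValueError("reduction_ratio and dim_floor must be >= 1")
        if len(self.branch_dilations) != 2:
            raise ValueError("exactly two SK branches are supported")
        if self.insertion not in ("per_dense_layer", "per_block", "none"):
            raise ValueError(f"unknown SK insertion mode: {self.insertion}")


def load_configs(path) -> tuple[ModelConfig, SKConfig | None]:
    """Read a YAML file with optional ``model:`` and ``sk:`` sections."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mk = dict(raw.get("model", {}))
    for key in ("block_layout",):
        if key in mk:
            mk[key] = tuple(mk[key])
    model_cfg = ModelConfig(**mk)
    sk_raw = raw.get("sk", None)
    if sk_raw is None:
        return model_cfg, None
    sk = dict(sk_raw)
    if "branch_dilations" in sk:
        sk["branch_dilations"] = tuple(sk["branch_dilations"])
    return model_cfg, SKConfig(**sk)


def sk_reduced_dim(channels: int, cfg: SKConfig) -> int:
    """Bottleneck dimension d = max(C / r, L)."""
    return max(channels // cfg.reduction_ratio, cfg.dim_floor)


class SKModule(Module):
    """Split (two dilated branches) / fuse (GAP + squeeze) / select (softmax gate)."""

    def __init__(self, channels: int, cfg: SKConfig, rng: np.random.Generator):
        super().__init__()
        groups = min(cfg.conv_groups, channels)
        if channels % groups:
            raise ValueError(
                f"SK branch groups ({groups}) must divide the operand channels ({channels})"
            )
        d1, d2 = cfg.branch_dilations
        self.branch1 = Sequential(
            Conv2d(channels, channels, 3, rng, padding=d1, dilation=d1, groups=groups),
            BatchNorm(channels), ReLU(),
        )
        self.branch2 = Sequential(
            Conv2d(channels, channels, 3, rng, padding=d2, dilation=d2, groups=groups),
            BatchNorm(channels), ReLU(),
        )
        d = sk_reduced_dim(channels, cfg)
        self.squeeze = Linear(channels, d, rng, bias=False)
        self.squeeze_bn = BatchNorm(d)
        self.gate_a = Linear(d, channels, rng, bias=False)
        self.gate_b = Linear(d, channels, rng, bias=False)
        self.last_gates: tuple[np.ndarray, np.ndarray] | None = None

    # the three SK stages, exposed individually
    def split(self, x: Tensor) -> tuple[Tensor, Tensor]:
        return self.branch1(x), self.branch2(x)

    def fuse(self, y1: Tensor, y2: Tensor) -> Tensor:
        s = F.global_avg_pool(y1 + y2)
        return F.relu(self.squeeze_bn(self.squeeze(s)))

    def select(self, z: Tensor, y1: Tensor, y2: Tensor) -> Tensor:
        la, lb = self.gate_a(z), self.gate_b(z)
        shift = np.maximum(la.data, lb.data)  # detached; softmax is shift-invariant
        ea, eb = F.exp(la - shift), F.exp(lb - shift)
        total = ea + eb
        a, b = ea / total, eb / total
        self.last_gates = (a.data.copy(), b.data.copy())
        n, c = a.shape
        return F.reshape(a, (n, c, 1, 1)) * y1 + F.reshape(b, (n, c, 1, 1)) * y2

    def forward(self, x: Tensor) -> Tensor:
        y1, y2 = self.split(x)
        z = self.fuse(y1, y2)
        return self.select(z, y1, y2)


class DenseLayer(Module):
    """BN-ReLU-1x1conv (bottleneck) -> BN-ReLU-3x3conv -> optional SK, yielding K channels."""

    def __init__(self, in_channels: int, growth_rate: int, bn_size: int,
                 rng: np.random.Generator, sk_cfg: SKConfig | None):
        super().__init__()
        width = bn_size * growth_rate
        self.norm1 = BatchNorm(in_channels)
        self.conv1 = Conv2d(in_channels, width, 1, rng)
        self.norm2 = BatchNorm(width)
        self.conv2 = Conv2d(width, growth_rate, 3, rng, padding=1)
        self.sk = (
            SKModule(growth_rate, sk_cfg, rng)
            if sk_cfg is not None and sk_cfg.insertion == "per_dense_layer"
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        out = self.conv1(F.relu(self.norm1(x)))
        out = self.conv2(F.relu(self.norm2(out)))
        if self.sk is not None:
            out = self.sk(out)
        return out


class DenseBlock(Module):
    """Each layer consumes the concatenation of the input and all previous outputs."""

    def __init__(self, in_channels: int, n_layers: int, growth_rate: int,
                 bn_size: int, rng: np.random.Generator, sk_cfg: SKConfig | None = None):
        super().__init__()
        self.layers = [
            DenseLayer(in_channels + i * growth_rate, growth_rate, bn_size, rng, sk_cfg)
            for i in range(n_layers)
        ]
        self.sk = (
            SKModule(in_channels + n_layers * growth_rate, sk_cfg, rng)
            if sk_cfg is not None and sk_cfg.insertion == "per_block" and n_layers > 0
            else None
        )
        self.out_channels = in_channels + n_layers * growth_rate

    def forward(self, x: Tensor) -> Tensor:
        features = [x]
        for layer in self.layers:
            inp = features[0] if len(features) == 1 else F.concat(features, axis=1)
            features.append(layer(inp))
        out = features[0] if len(features) == 1 else F.concat(features, axis=1)
        if self.sk is not None:
            out = self.sk(out)
        return out


class Transition(Module):
    """BN-ReLU-1x1conv channel compression followed by 2x2 average pooling."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.norm = BatchNorm(in_channels)
        self.conv = Conv2d(in_channels, out_channels, 1, rng)
        self.pool = AvgPool2d(2, 2)

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.conv(F.relu(self.norm(x))))


class DenseNetSK(Module):
    """DenseNet backbone with optional SK attention; outputs class logits."""

    def __init__(self, model_cfg: ModelConfig | None = None,
                 sk_cfg: SKConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = model_cfg or ModelConfig()
        self.config = cfg
        self.sk_config = sk_cfg
        rng = np.random.default_rng(seed)
        K = cfg.growth_rate
        init_features = 2 * K
        self.conv0 = Conv2d(cfg.in_channels, init_features, 7, rng, stride=2, padding=3)
        self.norm0 = BatchNorm(init_features)
        self.pool0 = MaxPool2d(3, 2, 1)

        sk = sk_cfg if sk_cfg is not None and sk_cfg.insertion != "none" else None
        self.blocks: list[Module] = []
        self.transitions: list[Module] = []
        channels = init_features
        for i, n_layers in enumerate(cfg.block_layout):
            block = DenseBlock(channels, n_layers, K, cfg.bn_size, rng, sk)
            self.blocks.append(block)
            channels = block.out_channels
            if i < len(cfg.block_layout) - 1:
                out = int(channels * cfg.compression)
                self.transitions.append(Transition(channels, out, rng))
                channels = out
        self.norm5 = BatchNorm(channels)
        self.classifier = Linear(channels, cfg.num_classes, rng)
        self.feature_channels = channels

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h = self.pool0(F.relu(self.norm0(self.conv0(x))))
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i < len(self.transitions):
                h = self.transitions[i](h)
        h = F.global_avg_pool(F.relu(self.norm5(h)))
        return self.classifier(h)

    # ------------------------------------------------------------------
    def parameter_report(self) -> dict:
        base = sk = 0
        for name, p in self.named_parameters():
            if ".sk." in f".{name}":
                sk += p.data.size
            else:
                base += p.data.size
        return {
            "base_params": base,
            "sk_params": sk,
            "total_params": base + sk,
            "base_millions": round(base / 1e6, 2),
            "sk_millions": round(sk / 1e6, 2),
            "total_millions": round((base + sk) / 1e6, 2),
        }


def build_model(model_cfg: ModelConfig | None = None, sk_cfg: SKConfig | None = None,
                seed: int = 0) -> tuple[DenseNetSK, dict]:
    """Construct the network and return it with its parameter report."""
    model = DenseNetSK(model_cfg, sk_cfg, seed=seed)
    return model, model.parameter_report()


def dense_block_forward(x: Tensor | np.ndarray, n_layers: int, growth_rate: int,
                        seed: int = 0) -> Tensor:
    """Run a standalone dense block on x; output channels = input + n_layers * K."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    block = DenseBlock(x.shape[1], n_layers, growth_rate, 4,
                       np.random.default_rng(seed), None)
    return block(x)


def focal_loss(probabilities, labels, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Mean focal loss -alpha (1 - p_t)^gamma log(p_t) over class probabilities.

    ``probabilities`` is an (N, K) matrix of class probabilities and
    ``labels`` the true class indices; gamma=0, alpha=1 reduces to plain
    cross-entropy. Zero probability at a true class is clamped with a
    warning.
    """
    p = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if p.ndim != 2 or len(labels) != p.shape[0]:
        raise ValueError("probabilities must be (N, K) with one label per row")
    pt = p[np.arange(len(labels)), labels]
    if np.any(pt <= 0):
        warnings.warn("zero probability at a true class; clamping", RuntimeWarning)
        pt = np.clip(pt, 1e-12, 1.0)
    return float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))
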