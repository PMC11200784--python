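"""CapnoNet: a compact multi-scale CNN for GAF-encoded capnograms.

Architecture (input 1×224×224 grayscale):

    conv 3×3 (1→32, bias-free) + BN + ReLU
    maxpool 2×2/s2  × 3                      (224 → 112 → 56 → 28)
    inception module 1: four parallel branches 32→26 with kernels
        1×1 / 3×3 / 5×5 / 7×7, each conv+BN+ReLU, concatenated → 104 ch
    maxpool 2×2/s2  × 2                      (28 → 14 → 7)
    inception module 2: four branches 104→108 → 432 ch at 7×7
    global average pool → 432-vector
    dropout 0.4
    fully connected 432 → n_classes  (softmax at inference)

All convolutions are stride 1 with zero-padding preserving spatial size;
downsampling happens only through pooling.  Every convolution is bias-free
because it is immediately followed by batch normalization.  With the binary
head this totals 1,015,666 trainable parameters (1.02 M) and a forward pass
costs 230,949,312 FLOPs (0.23 GFLOPs) counting conv and FC
multiply-accumulates times two.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "CapnoNet",
    "build_capnonet",
    "count_parameters",
    "count_flops",
]

KERNEL_SET = (1, 3, 5, 7)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Pinned CapnoNet hyperparameters."""

    in_side: int = 224
    stem_channels: int = 32
    inception1_width: int = 26
    inception2_width: int = 108
    kernel_sizes: tuple[int, ...] = KERNEL_SET
    pools_before_inception1: int = 3
    pools_before_inception2: int = 2
    dropout: float = 0.4
    n_classes: int = 2

    def __post_init__(self) -> None:
        if tuple(self.kernel_sizes) != KERNEL_SET:
            raise ValueError(f"kernel set must be exactly {KERNEL_SET}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        total_pools = self.pools_before_inception1 + self.pools_before_inception2
        if self.in_side % (2**total_pools) != 0:
            raise ValueError(
                f"in_side {self.in_side} not divisible by 2^{total_pools}"
            )

    @property
    def inception1_out(self) -> int:
        return len(self.kernel_sizes) * self.inception1_width

    @property
    def inception2_out(self) -> int:
        return len(self.kernel_sizes) * self.inception2_width

    @property
    def side_at_inception1(self) -> int:
        return self.in_side // 2**self.pools_before_inception1

    @property
    def side_at_inception2(self) -> int:
        return self.side_at_inception1 // 2**self.pools_before_inception2


class Inception(nn.Sequential):
    """Four parallel conv+BN+ReLU branches (kernels 1/3/5/7), concatenated."""

    def __init__(self, cin: int, width: int, kernels, rng: np.random.Generator):
        super().__init__()
        self.branches = [
            nn.Sequential(
                nn.Conv2d(cin, width, k, rng),
                nn.BatchNorm2d(width),
                nn.ReLU(),
            )
            for k in kernels
        ]
        self.layers = self.branches  # for param traversal
        self.width = width

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate(
            [b.forward(x, train=train) for b in self.branches], axis=1
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = None
        for i, b in enumerate(self.branches):
            sl = dout[:, i * self.width : (i + 1) * self.width]
            d = b.backward(np.ascontiguousarray(sl))
            dx = d if dx is None else dx + d
        return dx


class CapnoNet:
    """The assembled network with training/inference passes."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        self.net = nn.Sequential(
            nn.Conv2d(1, cfg.stem_channels, 3, rng, input_grad=False),
            nn.BatchNorm2d(cfg.stem_channels),
            nn.ReLU(),
            # consecutive 2x2/s2 pools run fused (identical output, one pass)
            nn.MaxPool2x2(stages=cfg.pools_before_inception1),
            Inception(cfg.stem_channels, cfg.inception1_width, cfg.kernel_sizes, rng),
            nn.MaxPool2x2(stages=cfg.pools_before_inception2),
            Inception(cfg.inception1_out, cfg.inception2_width, cfg.kernel_sizes, rng),
            nn.GlobalAvgPool(),
            nn.Dropout(cfg.dropout, self.dropout_rng),
            nn.Linear(cfg.inception2_out, cfg.n_classes, rng),
        )
        self._check_geometry()

    def _check_geometry(self) -> None:
        cfg = self.cfg
        assert cfg.side_at_inception2 >= 1, "network pools the image away"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of images, shape (B, 1, side, side) float32."""
        return self.net.forward(x.astype(np.float32), train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities at inference (dropout inactive)."""
        return nn.softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def param_layers(self):
        return self.net.param_layers()

    def state(self) -> list[np.ndarray]:
        """Flat copy of all trainable arrays (for determinism checks)."""
        return [
            p.copy() for layer in self.param_layers() for p in layer.params.values()
        ]


def build_capnonet(cfg: ModelConfig | None = None, seed: int = 0) -> CapnoNet:
    """Build a CapnoNet; identical config and seed give identical weights."""
    return CapnoNet(cfg or ModelConfig(), seed=seed)


def count_parameters(model: CapnoNet) -> int:
    """Total trainable scalars: conv weights, BN affine pairs, FC weight+bias."""
    return sum(layer.param_count() for layer in model.param_layers())


def count_flops(model: CapnoNet, in_side: int | None = None) -> int:
    """Forward-pass FLOPs = 2 × multiply-accumulates of convs and the FC layer.

    Convolution MACs are k²·Cin·Cout·H·W at each layer's spatial size; batch
    normalization, activations and pooling are excluded from the count.
    """
    cfg = model.cfg
    side = cfg.in_side if in_side is None else in_side
    k2sum = sum(k * k for k in cfg.kernel_sizes)
    s1 = side // 2**cfg.pools_before_inception1
    s2 = s1 // 2**cfg.pools_before_inception2
    macs = 9 * 1 * cfg.stem_channels * side * side
    macs += k2sum * cfg.stem_channels * cfg.inception1_width * s1 * s1
    macs += k2sum * cfg.inception1_out * cfg.inception2_width * s2 * s2
    macs += cfg.inception2_out * cfg.n_classes
    return 2 * macs
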