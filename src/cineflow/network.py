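"""The displacement-regression network: a residual U-Net with three deeply
supervised auxiliary heads.

The contracting path uses residual convolution blocks at four scales; the
first downsampling is a 2x2 max pool and the remaining three are stride-2
1x1 convolutions (which also expand the channel count). The expanding path
uses concatenation skip connections. A 2-channel (x/y displacement)
prediction head sits at decoder scales 1/8, 1/4 and 1/2 — each inserted
before the next upsampling and resampled to full resolution by nearest
neighbour — plus the final full-resolution head. All four predictions feed
the deep-supervision loss; the final head is the network output proper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .nn import (
    Adam,
    Conv1x1,
    ConvBlock,
    Module,
    ResidualBlock,
    Tensor,
    concat_channels,
    maxpool2x2,
    relu,
    upsample_nearest,
)
from .types import ValidationError

N_LEVELS = 4  # downsamplings; inputs must be divisible by 2**N_LEVELS


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``window`` is the number of input frames (central phase plus temporal
    neighbours, concatenated as channels). ``aux_weights`` are the deep
    supervision weights ``(w_1, w_2, w_3)`` of the three auxiliary heads,
    ordered coarsest (1/8 scale) to finest (1/2 scale).
    """

    window: int = 9
    base_channels: int = 32
    aux_weights: Tuple[float, float, float] = (0.25, 0.5, 0.75)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError(f"window must be odd and >= 3, got {self.window}")
        if any(w < 0 for w in self.aux_weights):
            raise ValidationError("aux_weights must be non-negative")
        if self.base_channels < 1:
            raise ValidationError("base_channels must be >= 1")

    @property
    def half_width(self) -> int:
        return self.window // 2


@dataclass
class NetworkOutput:
    """Four displacement predictions at full resolution.

    ``predictions[0:3]`` are the auxiliary heads (coarsest first);
    ``predictions[3]`` is the final output. Each is ``[2, H, W]``
    (x-displacement, y-displacement) in pixels per inter-frame interval.
    """

    predictions: List[np.ndarray]

    @property
    def final(self) -> np.ndarray:
        return self.predictions[3]


class FlowUNet(Module):
    """Residual U-Net mapping a frame window to a dense displacement field."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        C = cfg.base_channels
        w = cfg.window
        # contracting path
        self.enc0 = ResidualBlock(w, C, rng)
        self.enc1 = ResidualBlock(C, 2 * C, rng)
        self.down2 = Conv1x1(2 * C, 4 * C, rng, stride=2)
        self.enc2 = ResidualBlock(4 * C, 4 * C, rng)
        self.down3 = Conv1x1(4 * C, 8 * C, rng, stride=2)
        self.enc3 = ResidualBlock(8 * C, 8 * C, rng)
        self.down4 = Conv1x1(8 * C, 16 * C, rng, stride=2)
        self.enc4 = ResidualBlock(16 * C, 16 * C, rng)
        # expanding path
        self.dec3 = ConvBlock(16 * C + 8 * C, 8 * C, rng)
        self.dec2 = ConvBlock(8 * C + 4 * C, 4 * C, rng)
        self.dec1 = ConvBlock(4 * C + 2 * C, 2 * C, rng)
        self.dec0 = ConvBlock(2 * C + C, C, rng)
        # prediction heads (2 channels: dx, dy)
        self.aux_head3 = Conv1x1(8 * C, 2, rng)
        self.aux_head2 = Conv1x1(4 * C, 2, rng)
        self.aux_head1 = Conv1x1(2 * C, 2, rng)
        self.final_head = Conv1x1(C, 2, rng)

    def forward(self, x: Tensor, training: bool = False) -> List[Tensor]:
        """Run a batch ``[N, window, H, W]``; returns the four prediction
        tensors ``[N, 2, H, W]``, auxiliary (coarse to fine) then final."""
        H, W = x.data.shape[2], x.data.shape[3]
        if H % 2**N_LEVELS or W % 2**N_LEVELS:
            raise ValidationError(
                f"input size ({H},{W}) not divisible by {2**N_LEVELS}; pad or crop first"
            )
        e0 = self.enc0(x, training)                      # C,   1/1
        e1 = self.enc1(maxpool2x2(e0), training)         # 2C,  1/2
        e2 = self.enc2(relu(self.down2(e1)), training)   # 4C,  1/4
        e3 = self.enc3(relu(self.down3(e2)), training)   # 8C,  1/8
        e4 = self.enc4(relu(self.down4(e3)), training)   # 16C, 1/16

        y3 = self.dec3(concat_channels(upsample_nearest(e4, 2), e3), training)  # 1/8
        aux1 = upsample_nearest(self.aux_head3(y3), 8)
        y2 = self.dec2(concat_channels(upsample_nearest(y3, 2), e2), training)  # 1/4
        aux2 = upsample_nearest(self.aux_head2(y2), 4)
        y1 = self.dec1(concat_channels(upsample_nearest(y2, 2), e1), training)  # 1/2
        aux3 = upsample_nearest(self.aux_head1(y1), 2)
        y0 = self.dec0(concat_channels(upsample_nearest(y1, 2), e0), training)  # 1/1
        final = self.final_head(y0)
        return [aux1, aux2, aux3, final]

    def __call__(self, stack: np.ndarray) -> NetworkOutput:
        """Predict from a single ``[window, H, W]`` frame stack (inference)."""
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim != 3 or stack.shape[0] != self.cfg.window:
            raise ValidationError(
                f"expected [{self.cfg.window},H,W] stack, got {stack.shape}"
            )
        outs = self.forward(Tensor(stack[None]), training=False)
        return NetworkOutput(predictions=[o.data[0] for o in outs])

    def manifest(self) -> str:
        """JSON architecture description for reproducibility."""
        return json.dumps(
            {
                "architecture": "residual U-Net, deep supervision (3 aux heads)",
                "window": self.cfg.window,
                "base_channels": self.cfg.base_channels,
                "levels": N_LEVELS,
                "downsampling": ["maxpool2x2", "conv1x1/s2", "conv1x1/s2", "conv1x1/s2"],
                "aux_weights": list(self.cfg.aux_weights),
                "n_parameters": self.n_parameters(),
                "seed": self.cfg.seed,
            },
            indent=2,
        )

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def save(self, path) -> None:
        np.savez_compressed(path, *[p.data for p in self.parameters()])

    def load(self, path) -> None:
        with np.load(path) as z:
            arrays = [z[k] for k in z.files]
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValidationError("checkpoint does not match architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValidationError("checkpoint parameter shape mismatch")
            p.data = a.astype(np.float64)


def build_network(cfg: NetworkConfig) -> FlowUNet:
    """Construct a :class:`FlowUNet` with deterministic seeded initialization."""
    return FlowUNet(cfg)


def make_optimizer(net: FlowUNet, lr: float = 1e-3) -> Adam:
    return Adam(net.parameters(), lr=lr)
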