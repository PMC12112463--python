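"""Dual-path downsampler (DPDown).

The block halves the spatial resolution while keeping two complementary
views of the feature map. The input is first smoothed with a 2x2 stride-1
average pool, then split in half along channels. The first half goes through
a 3x3 stride-2 convolution (local detail); the second half goes through a
3x3 stride-2 max pool followed by a 1x1 convolution (salient context). The
two halves are concatenated back along channels:

    x   <- AvgPool(x, k=2, s=1)
    x1, x2 <- split channels in half
    y1  <- Conv3x3(x1, s=2, p=1)
    y2  <- Conv1x1(MaxPool(x2, k=3, s=2, p=1))
    y   <- Concat(y1, y2)

The average pool shrinks each spatial dim by one; the stride-2 padding-1
stages then map an even H x W input to exactly H/2 x W/2. Odd spatial sizes
are rejected so the halving contract stays exact. The block contains no
normalization or activation — callers wrap it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .nn import AvgPool2d, Conv2d, MaxPool2d, Param

__all__ = ["DPDownConfig", "DPDown", "dpdown_output_shape"]


@dataclass(frozen=True)
class DPDownConfig:
    """Channel contract; both counts must be even (each branch takes half)."""

    in_channels: int
    out_channels: int

    def __post_init__(self):
        if self.in_channels < 2 or self.in_channels % 2:
            raise ValueError(f"in_channels must be even and >= 2, got {self.in_channels}")
        if self.out_channels < 2 or self.out_channels % 2:
            raise ValueError(f"out_channels must be even and >= 2, got {self.out_channels}")

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "out_channels": self.out_channels}

    @classmethod
    def from_dict(cls, d: dict) -> "DPDownConfig":
        return cls(int(d["in_channels"]), int(d["out_channels"]))


def dpdown_output_shape(h: int, w: int, cfg: DPDownConfig) -> Tuple[int, int, int]:
    """Predicted output shape (out_channels, h/2, w/2) for even h, w >= 4."""
    if h < 4 or w < 4:
        raise ValueError(f"spatial dims must be >= 4, got {h}x{w}")
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even, got {h}x{w}")
    # avg pool k2 s1: (h-1); conv/pool k3 s2 p1: floor((h-1+2-3)/2)+1 = h/2
    return (cfg.out_channels, (h - 2) // 2 + 1, (w - 2) // 2 + 1)


class DPDown:
    """Downsampling block with a convolutional and a pooling branch."""

    def __init__(self, cfg: DPDownConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        half_in = cfg.in_channels // 2
        half_out = cfg.out_channels // 2
        self.avg = AvgPool2d(kernel_size=2, stride=1)
        self.conv3 = Conv2d(half_in, half_out, 3, stride=2, padding=1, rng=rng)
        self.maxpool = MaxPool2d(kernel_size=3, stride=2, padding=1)
        self.conv1 = Conv2d(half_in, half_out, 1, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {c}")
        dpdown_output_shape(h, w, self.cfg)  # validates spatial size
        xs = self.avg.forward(x)
        half = c // 2
        x1, x2 = xs[:, :half], xs[:, half:]
        y1 = self.conv3.forward(x1)
        y2 = self.conv1.forward(self.maxpool.forward(x2))
        return np.concatenate([y1, y2], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        half_out = self.cfg.out_channels // 2
        dy1, dy2 = dy[:, :half_out], dy[:, half_out:]
        dx1 = self.conv3.backward(dy1)
        dx2 = self.maxpool.backward(self.conv1.backward(dy2))
        return self.avg.backward(np.concatenate([dx1, dx2], axis=1))

    def params(self) -> List[Param]:
        return self.conv3.params() + self.conv1.params()
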