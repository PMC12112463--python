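"""Reparameterized dilated fusion block (RDFBlock).

During training the block runs a large K x K convolution in parallel with
several small dilated convolutions, sums the branch outputs, and applies one
batch normalization followed by ReLU:

    y = ReLU(BN(W_std * x + sum_i W_dil,i *_{r_i} x))

A small kernel of size k at dilation rate r covers an equivalent receptive
field R = k + (k-1)(r-1). Because every branch is linear and shares the same
output, the multi-branch structure collapses exactly at deployment: each
dilated kernel is rewritten as a dense R x R kernel (taps spread out with
zeros in between), zero-embedded into the K x K field, and summed with the
large kernel,

    W_deploy = W_std + sum_i embed(dilate(W_dil,i, r_i), K),

so inference needs a single convolution with bit-equal output (up to float
rounding) when batch norm runs on frozen statistics.

Branch convolutions carry no bias (the batch norm absorbs any shift), stride
is fixed at 1 and kernels are odd, which keeps the center embedding exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import BatchNorm2d, Conv2d, ReLU, Param, conv2d

__all__ = [
    "BranchSpec",
    "RDFConfig",
    "RDFWeights",
    "receptive_field",
    "dilate_kernel",
    "embed_center",
    "rdf_fuse",
    "RDFBlock",
    "save_rdf_archive",
    "load_rdf_archive",
]

DEFAULT_BRANCHES: Tuple[Tuple[int, int], ...] = ((5, 1), (3, 2), (3, 3))


def receptive_field(k: int, r: int) -> int:
    """Equivalent receptive field R = k + (k-1)(r-1) of a dilated kernel."""
    if k < 1 or r < 1:
        raise ValueError(f"kernel size and dilation must be >= 1, got k={k}, r={r}")
    return k + (k - 1) * (r - 1)


@dataclass(frozen=True)
class BranchSpec:
    """One dilated branch: kernel size k (odd) at integer dilation rate r."""

    k: int
    r: int

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"kernel size must be odd and positive, got {self.k}")
        if self.r < 1:
            raise ValueError(f"dilation rate must be >= 1, got {self.r}")

    @property
    def R(self) -> int:
        return receptive_field(self.k, self.r)


@dataclass(frozen=True)
class RDFConfig:
    in_channels: int
    out_channels: int
    K: int = 7
    branches: Tuple[BranchSpec, ...] = field(
        default_factory=lambda: tuple(BranchSpec(k, r) for k, r in DEFAULT_BRANCHES)
    )
    groups: int = 1

    def __post_init__(self):
        object.__setattr__(
            self,
            "branches",
            tuple(b if isinstance(b, BranchSpec) else BranchSpec(*b) for b in self.branches),
        )
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError("groups must divide both channel counts")
        if self.K < 1 or self.K % 2 == 0:
            raise ValueError(f"large kernel K must be odd, got {self.K}")
        for b in self.branches:
            if b.R > self.K:
                raise ValueError(f"branch {b} has receptive field {b.R} exceeding K={self.K}")

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "K": self.K,
            "branches": [[b.k, b.r] for b in self.branches],
            "groups": self.groups,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RDFConfig":
        return cls(
            in_channels=int(d["in_channels"]),
            out_channels=int(d["out_channels"]),
            K=int(d["K"]),
            branches=tuple(BranchSpec(int(k), int(r)) for k, r in d["branches"]),
            groups=int(d.get("groups", 1)),
        )


@dataclass
class RDFWeights:
    """All learnable state of one block, as plain arrays."""

    w_std: np.ndarray
    w_dil: List[np.ndarray]
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray
    bn_eps: float = 1e-5


def dilate_kernel(w: np.ndarray, r: int) -> np.ndarray:
    """Spread a (..., k, k) kernel to its dense (..., R, R) equivalent.

    Taps land at positions (i*r, j*r); everything in between is zero, so a
    dilation-1 convolution with the result equals a dilation-r convolution
    with the original.
    """
    if r < 1:
        raise ValueError(f"dilation must be >= 1, got {r}")
    if r == 1:
        return w.copy()
    k1, k2 = w.shape[-2], w.shape[-1]
    out = np.zeros(w.shape[:-2] + ((k1 - 1) * r + 1, (k2 - 1) * r + 1), dtype=w.dtype)
    out[..., ::r, ::r] = w
    return out


def embed_center(w: np.ndarray, K: int) -> np.ndarray:
    """Zero-pad a dense (..., R, R) kernel symmetrically into (..., K, K)."""
    R1, R2 = w.shape[-2], w.shape[-1]
    if R1 != R2:
        raise ValueError("kernel must be square")
    if R1 > K:
        raise ValueError(f"kernel size {R1} exceeds target {K}")
    if (K - R1) % 2:
        raise ValueError(f"parity mismatch embedding {R1} into {K}")
    if R1 == K:
        return w.copy()
    off = (K - R1) // 2
    out = np.zeros(w.shape[:-2] + (K, K), dtype=w.dtype)
    out[..., off : off + R1, off : off + R2] = w
    return out


def rdf_fuse(cfg: RDFConfig, wts: RDFWeights) -> np.ndarray:
    """Collapse the multi-branch weights into one K x K deploy kernel."""
    if len(wts.w_dil) != len(cfg.branches):
        raise ValueError(
            f"weight/branch mismatch: {len(wts.w_dil)} weight arrays, {len(cfg.branches)} branches"
        )
    fused = wts.w_std.copy()
    for spec, w in zip(cfg.branches, wts.w_dil):
        if w.shape[-1] != spec.k:
            raise ValueError(f"branch kernel shape {w.shape} does not match spec k={spec.k}")
        fused += embed_center(dilate_kernel(w, spec.r), cfg.K)
    return fused


class RDFBlock:
    """Trainable block: parallel dilated branches, one BN, ReLU, exact fusion."""

    def __init__(
        self,
        cfg: RDFConfig,
        rng: Optional[np.random.Generator] = None,
        residual: bool = False,
    ):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        if residual and cfg.in_channels != cfg.out_channels:
            raise ValueError("residual wrapper requires in_channels == out_channels")
        self.residual = residual
        self.conv_std = Conv2d(
            cfg.in_channels,
            cfg.out_channels,
            cfg.K,
            padding=cfg.K // 2,
            groups=cfg.groups,
            bias=False,
            rng=rng,
        )
        self.conv_dil = [
            Conv2d(
                cfg.in_channels,
                cfg.out_channels,
                b.k,
                padding=b.R // 2,
                dilation=b.r,
                groups=cfg.groups,
                bias=False,
                rng=rng,
            )
            for b in cfg.branches
        ]
        self.bn = BatchNorm2d(cfg.out_channels)
        self.relu = ReLU()
        self._fused: Optional[np.ndarray] = None

    # -- training path ------------------------------------------------------
    def forward_train(self, x: np.ndarray, bn_mode: str = "batch_stats") -> np.ndarray:
        s = self.conv_std.forward(x)
        for conv in self.conv_dil:
            s = s + conv.forward(x)
        y = self.relu.forward(self.bn.forward(s, mode=bn_mode))
        return y + x if self.residual else y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ds = self.bn.backward(self.relu.backward(dy))
        dx = self.conv_std.backward(ds)
        for conv in self.conv_dil:
            dx = dx + conv.backward(ds)
        return dx + dy if self.residual else dx

    def params(self) -> List[Param]:
        ps = self.conv_std.params()
        for conv in self.conv_dil:
            ps += conv.params()
        return ps + self.bn.params()

    # -- weights / fusion ----------------------------------------------------
    def get_weights(self) -> RDFWeights:
        return RDFWeights(
            w_std=self.conv_std.weight.data.copy(),
            w_dil=[c.weight.data.copy() for c in self.conv_dil],
            bn_gamma=self.bn.gamma.data.copy(),
            bn_beta=self.bn.beta.data.copy(),
            bn_mean=self.bn.running_mean.copy(),
            bn_var=self.bn.running_var.copy(),
            bn_eps=self.bn.eps,
        )

    def set_weights(self, wts: RDFWeights) -> None:
        self.conv_std.weight.data = wts.w_std.copy()
        for conv, w in zip(self.conv_dil, wts.w_dil):
            conv.weight.data = w.copy()
        self.bn.gamma.data = wts.bn_gamma.copy()
        self.bn.beta.data = wts.bn_beta.copy()
        self.bn.running_mean = wts.bn_mean.copy()
        self.bn.running_var = wts.bn_var.copy()
        self.bn.eps = wts.bn_eps
        self._fused = None

    def fuse(self) -> np.ndarray:
        """Compute (and cache) the deploy kernel."""
        self._fused = rdf_fuse(self.cfg, self.get_weights())
        return self._fused

    def forward_deploy(self, x: np.ndarray) -> np.ndarray:
        """Single-convolution inference path on frozen BN statistics."""
        if self._fused is None:
            self.fuse()
        y = conv2d(x, self._fused, padding=self.cfg.K // 2, groups=self.cfg.groups)
        y = self.relu.forward(self.bn.forward(y, mode="running_stats"))
        return y + x if self.residual else y


# ---------------------------------------------------------------------------
# weight archive: flat .npz plus a JSON/YAML config sidecar
# ---------------------------------------------------------------------------


def save_rdf_archive(
    path: str | Path,
    cfg: RDFConfig,
    wts: RDFWeights,
    fused: Optional[np.ndarray] = None,
) -> None:
    """Write weights to ``<path>`` (.npz) and the config to a JSON sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    arrays = {
        "w_std": wts.w_std,
        "bn_gamma": wts.bn_gamma,
        "bn_beta": wts.bn_beta,
        "bn_mean": wts.bn_mean,
        "bn_var": wts.bn_var,
        "bn_eps": np.array(wts.bn_eps),
    }
    for i, w in enumerate(wts.w_dil):
        arrays[f"w_dil_{i}"] = w
    if fused is not None:
        arrays["w_deploy"] = fused
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(cfg.to_dict(), indent=2))


def load_rdf_archive(path: str | Path) -> Tuple[RDFConfig, RDFWeights, Optional[np.ndarray]]:
    """Load an archive written by :func:`save_rdf_archive`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing config sidecar {sidecar}")
    cfg = RDFConfig.from_dict(json.loads(sidecar.read_text()))
    with np.load(path) as npz:
        keys = set(npz.files)
        required = {"w_std", "bn_gamma", "bn_beta", "bn_mean", "bn_var"}
        missing = required - keys
        if missing:
            raise KeyError(f"archive {path} missing keys: {sorted(missing)}")
        w_dil = []
        for i in range(len(cfg.branches)):
            key = f"w_dil_{i}"
            if key not in keys:
                raise KeyError(f"archive {path} missing branch weights {key}")
            w_dil.append(npz[key])
        wts = RDFWeights(
            w_std=npz["w_std"],
            w_dil=w_dil,
            bn_gamma=npz["bn_gamma"],
            bn_beta=npz["bn_beta"],
            bn_mean=npz["bn_mean"],
            bn_var=npz["bn_var"],
            bn_eps=float(npz["bn_eps"]) if "bn_eps" in keys else 1e-5,
        )
        fused = npz["w_deploy"] if "w_deploy" in keys else None
    return cfg, wts, fused
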