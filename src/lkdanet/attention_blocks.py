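"""Building blocks of the large-kernel depthwise-convolution attention network.

The token mixer ("LKD attention") emulates windowed self-attention with a
cascade of two large depthwise convolutions — kernel 5 with dilation 1
followed by kernel 7 with dilation 3 — giving each output voxel an
effective receptive field of 23 voxels per axis at depthwise cost.  The
two branch outputs are gated by sigmoid spatial weights derived from
channel-wise average/max pooling, recalibrated by a squeeze-and-excitation
gate, and finally applied multiplicatively to the block input with a
residual connection.

The channel mixer ("DWCA") is an inverted bottleneck that expands every
channel to ``expansion`` copies and compresses back using only per-channel
scalars, so it carries exactly ``(3·expansion + 1)·C`` learnable
parameters and never mixes channels.

A full block stacks the two as pre-norm residual sublayers::

    z_hat = z + LKDAttention(LN(z))
    z_out = z_hat + DWCA(LN(z_hat))

with layer normalisation taken channel-wise at each voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import core as F


class ConfigurationError(ValueError):
    """Raised when a block is configured inconsistently."""


@dataclass(frozen=True)
class LKDAttentionConfig:
    """Hyperparameters of the LKD attention token mixer.

    channels
        Block width C; must be even because the input projection halves it.
    branch1, branch2
        (kernel, dilation) of the two cascaded depthwise convolutions.
    mix_kernel
        Kernel of the dense 2→2 convolution that mixes the pooled
        average/max spatial statistics before the sigmoid.
    se_reduction
        Bottleneck ratio r of the squeeze-and-excitation gate on the C/2
        branch feature.
    """

    channels: int
    branch1: tuple[int, int] = (5, 1)
    branch2: tuple[int, int] = (7, 3)
    mix_kernel: int = 5
    se_reduction: int = 4

    def __post_init__(self):
        if self.channels < 2 or self.channels % 2:
            raise ConfigurationError(
                f"LKD attention needs an even channel count (the projection "
                f"halves it); got {self.channels}")
        for k, _ in (self.branch1, self.branch2):
            if k % 2 == 0:
                raise ConfigurationError(f"kernels must be odd, got {k}")
        if self.mix_kernel % 2 == 0:
            raise ConfigurationError(
                f"mix kernel must be odd, got {self.mix_kernel}")
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be >= 1")
        if self.channels // 2 < self.se_reduction:
            raise ConfigurationError(
                f"se_reduction {self.se_reduction} exceeds the branch width "
                f"{self.channels // 2}")


@dataclass(frozen=True)
class DWCAConfig:
    """Hyperparameters of the per-channel inverted bottleneck."""

    channels: int
    expansion: int = 4

    def __post_init__(self):
        if self.channels < 1:
            raise ConfigurationError(f"channels must be >= 1, got {self.channels}")
        if self.expansion < 1:
            raise ConfigurationError(f"expansion must be >= 1, got {self.expansion}")


def _check_volume(x: Tensor) -> None:
    if x.ndim != 5:
        raise ValueError(f"expected a rank-5 (N, C, D, H, W) volume, "
                         f"got rank {x.ndim}")


class SqueezeExcite(nn.Module):
    """Squeeze-and-excitation channel gate.

    Global average pool → bottleneck C→C/r→C (ReLU, then sigmoid) →
    per-channel multiplicative gate in (0, 1).
    """

    def __init__(self, channels: int, reduction: int, *,
                 rng: np.random.Generator):
        super().__init__()
        if reduction > channels:
            raise ConfigurationError(
                f"SE reduction {reduction} exceeds channel count {channels}")
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        """The per-channel gate values, shape (N, C), each in (0, 1)."""
        squeezed = F.global_avg_pool(x)
        return F.sigmoid(self.fc2(F.relu(self.fc1(squeezed))))

    def forward(self, x: Tensor) -> Tensor:
        _check_volume(x)
        g = self.gate(x)
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1, 1)


class LKDAttention(nn.Module):
    """Large-kernel depthwise convolution attention (the token mixer).

    Pipeline on an input ``x`` with C channels::

        X  = project_halve(x)                      # 1×1×1, C → C/2
        X1 = DWConv(k=5, d=1)(X)                   # cascade, stage 1
        X2 = DWConv(k=7, d=3)(X1)                  # cascade, stage 2
        X3 = concat(X1, X2)                        # back to C channels
        w1, w2 = spatial_weights(X3)               # sigmoid maps in (0,1)
        X4 = w1·X1 + w2·X2                         # branch selection, C/2
        w3 = Conv1x1(SE(X4))                       # C/2 → C gate
        out = w3·x + x                             # gated residual
    """

    def __init__(self, cfg: LKDAttentionConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C = cfg.channels
        half = C // 2
        k1, d1 = cfg.branch1
        k2, d2 = cfg.branch2
        self.proj = nn.Conv3d(C, half, 1, rng=rng)
        self.dw1 = nn.Conv3d(half, half, k1, padding=(k1 - 1) // 2 * d1,
                             dilation=d1, groups=half, rng=rng)
        self.dw2 = nn.Conv3d(half, half, k2, padding=(k2 - 1) // 2 * d2,
                             dilation=d2, groups=half, rng=rng)
        self.mix = nn.Conv3d(2, 2, cfg.mix_kernel,
                             padding=(cfg.mix_kernel - 1) // 2, rng=rng)
        self.se = SqueezeExcite(half, cfg.se_reduction, rng=rng)
        self.out_proj = nn.Conv3d(half, C, 1, rng=rng)

    # -- pipeline stages, individually testable ----------------------------

    def project_halve(self, x: Tensor) -> Tensor:
        """Learned 1×1×1 projection halving the channel count."""
        _check_volume(x)
        if x.shape[1] != self.cfg.channels:
            raise ConfigurationError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        return self.proj(x)

    def cascade_dw(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """The two cascaded depthwise branch outputs (X1, X2)."""
        x1 = self.dw1(x)
        x2 = self.dw2(x1)
        return x1, x2

    def spatial_weights(self, x3: Tensor) -> tuple[Tensor, Tensor]:
        """Sigmoid spatial selection maps from channel avg/max pooling.

        Returns two single-channel volumes, each strictly inside (0, 1).
        """
        stats = F.concat([F.channel_mean(x3), F.channel_max(x3)], axis=1)
        mixed = F.sigmoid(self.mix(stats))
        return F.narrow(mixed, 1, 0, 1), F.narrow(mixed, 1, 1, 1)

    def gated(self, x: Tensor) -> Tensor:
        """The attention contribution w3 ⊗ x, without the residual.

        This is the sublayer term a pre-norm block adds onto its stream;
        it vanishes identically when the output projection is zeroed.
        """
        xp = self.project_halve(x)
        x1, x2 = self.cascade_dw(xp)
        x3 = F.concat([x1, x2], axis=1)
        w1, w2 = self.spatial_weights(x3)
        x4 = w1 * x1 + w2 * x2
        w3 = self.out_proj(self.se(x4))
        return w3 * x

    def forward(self, x: Tensor) -> Tensor:
        return self.gated(x) + x


class DWCA(nn.Module):
    """Inverted bottleneck with depthwise (per-channel) augmentation.

    Each channel is expanded to ``expansion`` copies by learned scalars
    (grouped 1×1×1 convolution with channel multiplier m), passed through
    GELU, and compressed back by another set of per-channel scalars.  No
    cross-channel weights exist anywhere; with m=4 the parameter count is
    exactly 13·C.
    """

    def __init__(self, cfg: DWCAConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C, m = cfg.channels, cfg.expansion
        self.expand = nn.Conv3d(C, C * m, 1, groups=C, rng=rng)
        self.compress = nn.Conv3d(C * m, C, 1, groups=C, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_volume(x)
        return self.compress(F.gelu(self.expand(x)))


class LKDABlock(nn.Module):
    """One encoder block: pre-norm token mixer + pre-norm channel mixer."""

    def __init__(self, channels: int, *, rng: np.random.Generator,
                 attention: LKDAttentionConfig | None = None,
                 dwca: DWCAConfig | None = None):
        super().__init__()
        acfg = attention or LKDAttentionConfig(channels)
        dcfg = dwca or DWCAConfig(channels)
        if acfg.channels != channels or dcfg.channels != channels:
            raise ConfigurationError("sublayer configs disagree on channels")
        self.norm1 = nn.LayerNorm3d(channels)
        self.attn = LKDAttention(acfg, rng=rng)
        self.norm2 = nn.LayerNorm3d(channels)
        self.dwca = DWCA(dcfg, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        # pre-norm residual stream: each sublayer adds its contribution to
        # the un-normalised input, so zeroed sublayers leave z untouched
        z_hat = z + self.attn.gated(self.norm1(z))
        return z_hat + self.dwca(self.norm2(z_hat))
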