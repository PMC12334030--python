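"""The full U-shaped encoder–decoder segmentation network.

Five encoder stages produce features at scales 1/2 … 1/32 of the input
with widths doubling from 48 to 768: a large-kernel (7³, stride 2) patch
embedding, then four stages of strided 2³ downsampling followed by a run
of attention blocks.  The decoder climbs back up with trilinear ×2
upsampling blocks, fusing each scale with the matching encoder feature
through a two-path convolutional fusion module, and emits per-voxel class
logits at full input resolution (plus coarse auxiliary logits for deep
supervision).

Architecture analyzers live here too: exact learnable-parameter counting
(closed form and by enumeration) and the analytic effective receptive
field of a convolution chain.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .nn import core as F
from .attention_blocks import (ConfigurationError, DWCAConfig,
                               LKDAttentionConfig, LKDABlock)

#: Default blocks per stage (stages 2-5).  The stage widths and kernel plan
#: are fixed by the architecture; the per-stage depth is a free knob,
#: calibrated so the reference configuration (1 input channel, 9 classes)
#: lands on the reference 48.52 M learnable-parameter budget.
DEFAULT_STAGE_DEPTHS = (2, 4, 6, 23)


@dataclass(frozen=True)
class LKDANetConfig:
    """Complete architecture hyperparameters.

    stage_channels must be strictly increasing and even; the default
    follows the reference width plan (48 at 1/2 resolution doubling to 768
    at 1/32).  stage_depths gives the number of attention blocks in stages
    2-5 (stage 1 is the patch embedding alone).
    """

    num_classes: int
    in_channels: int = 1
    stage_channels: tuple[int, ...] = (48, 96, 192, 384, 768)
    stage_depths: tuple[int, ...] = DEFAULT_STAGE_DEPTHS
    deep_supervision: bool = True
    patch_kernel: int = 7
    down_kernel: int = 2
    branch1: tuple[int, int] = (5, 1)
    branch2: tuple[int, int] = (7, 3)
    mix_kernel: int = 5
    se_reduction: int = 4
    dwca_expansion: int = 4

    def __post_init__(self):
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be >= 1")
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be >= 1")
        ch = tuple(self.stage_channels)
        if len(ch) != 5:
            raise ConfigurationError("stage_channels must list 5 stages")
        if any(c % 2 for c in ch):
            raise ConfigurationError(f"stage channels must be even: {ch}")
        if any(b <= a for a, b in zip(ch, ch[1:])):
            raise ConfigurationError(f"stage channels must increase: {ch}")
        if len(tuple(self.stage_depths)) != 4:
            raise ConfigurationError("stage_depths covers stages 2-5 (4 entries)")
        if any(d < 1 for d in self.stage_depths):
            raise ConfigurationError("stage depths must be >= 1")

    def attention_config(self, channels: int) -> LKDAttentionConfig:
        return LKDAttentionConfig(channels, branch1=self.branch1,
                                  branch2=self.branch2,
                                  mix_kernel=self.mix_kernel,
                                  se_reduction=self.se_reduction)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LKDANetConfig":
        d = dict(d)
        for key in ("stage_channels", "stage_depths", "branch1", "branch2"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config(num_classes: int = 9, **overrides) -> LKDANetConfig:
    """The reference architecture (9 classes: 8 organs + background)."""
    return LKDANetConfig(num_classes=num_classes, **overrides)


# ---------------------------------------------------------------------------
# receptive field


def effective_receptive_field(chain) -> int:
    """Per-axis receptive-field extent of a unit-stride convolution chain.

    For kernels k_i with dilations d_i the extent is ``1 + Σ (k_i − 1)·d_i``:
    each layer widens the set of contributing input voxels by (k−1)·d per
    axis.  The default attention cascade [(5,1), (7,3)] gives 23.
    """
    chain = list(chain)
    if not chain:
        raise ValueError("kernel chain must be non-empty")
    extent = 1
    for k, d in chain:
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernels must be odd and positive, got {k}")
        if d < 1:
            raise ValueError(f"dilations must be positive, got {d}")
        extent += (k - 1) * d
    return extent


# ---------------------------------------------------------------------------
# component modules


class PatchEmbed(nn.Module):
    """Dense 7³ stride-2 convolution turning the raw volume into tokens."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv3d(in_channels, out_channels, kernel, stride=2,
                              padding=(kernel - 1) // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        sp = x.shape[2:]
        if any(s < 2 or s % 2 for s in sp):
            raise ValueError(
                f"patch embedding halves the volume; spatial dims must be "
                f"even and >= 2, got {tuple(sp)} — pad or crop the input")
        return self.conv(x)


class Downsample(nn.Module):
    """2³ stride-2 convolution halving resolution and doubling width."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv3d(in_channels, out_channels, kernel, stride=2,
                              rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"downsampling needs even spatial dims, "
                             f"got {tuple(x.shape[2:])}")
        return self.conv(x)


class UpsampleBlock(nn.Module):
    """Trilinear ×2 upsampling, then conv(3³) → BatchNorm → ReLU."""

    def __init__(self, in_channels: int, out_channels: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv3d(in_channels, out_channels, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm3d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        size = tuple(2 * s for s in x.shape[2:])
        return F.relu(self.bn(self.conv(F.interpolate(x, size))))


class SkipFusion(nn.Module):
    """Two-path skip-connection fusion.

    Encoder and decoder features are refined by separate 3³ convolutions
    (conv → GELU → BatchNorm on each path), concatenated to 2C channels,
    and fused through an inverted bottleneck of two pointwise convolutions
    2C → 4C → C, each likewise followed by GELU and BatchNorm.
    """

    def __init__(self, channels: int, *, rng: np.random.Generator):
        super().__init__()
        C = channels
        self.conv_enc = nn.Conv3d(C, C, 3, padding=1, rng=rng)
        self.bn_enc = nn.BatchNorm3d(C)
        self.conv_dec = nn.Conv3d(C, C, 3, padding=1, rng=rng)
        self.bn_dec = nn.BatchNorm3d(C)
        self.pw1 = nn.Conv3d(2 * C, 4 * C, 1, rng=rng)
        self.bn1 = nn.BatchNorm3d(4 * C)
        self.pw2 = nn.Conv3d(4 * C, C, 1, rng=rng)
        self.bn2 = nn.BatchNorm3d(C)

    def forward(self, f_enc: Tensor, f_dec: Tensor) -> Tensor:
        if f_enc.shape != f_dec.shape:
            raise ValueError(f"skip fusion needs matching shapes, got "
                             f"encoder {tuple(f_enc.shape)} vs "
                             f"decoder {tuple(f_dec.shape)}")
        e = self.bn_enc(F.gelu(self.conv_enc(f_enc)))
        d = self.bn_dec(F.gelu(self.conv_dec(f_dec)))
        fc = F.concat([e, d], axis=1)
        h = self.bn1(F.gelu(self.pw1(fc)))
        return self.bn2(F.gelu(self.pw2(h)))


# ---------------------------------------------------------------------------
# encoder / decoder / full model


class LKDAEncoder(nn.Module):
    def __init__(self, cfg: LKDANetConfig, *, rng: np.random.Generator):
        super().__init__()
        ch = cfg.stage_channels
        self.patch_embed = PatchEmbed(cfg.in_channels, ch[0],
                                      cfg.patch_kernel, rng=rng)
        self.downsamples = nn.ModuleList()
        self.stages = nn.ModuleList()
        for i in range(4):
            self.downsamples.append(
                Downsample(ch[i], ch[i + 1], cfg.down_kernel, rng=rng))
            blocks = nn.ModuleList(
                LKDABlock(ch[i + 1], rng=rng,
                          attention=cfg.attention_config(ch[i + 1]),
                          dwca=DWCAConfig(ch[i + 1], cfg.dwca_expansion))
                for _ in range(cfg.stage_depths[i]))
            self.stages.append(blocks)

    def forward(self, x: Tensor) -> list[Tensor]:
        sp = x.shape[2:]
        if any(s % 32 for s in sp):
            raise ValueError(f"encoder needs spatial dims divisible by 32, "
                             f"got {tuple(sp)}")
        feats = [self.patch_embed(x)]
        h = feats[0]
        for down, blocks in zip(self.downsamples, self.stages):
            h = down(h)
            for blk in blocks:
                h = blk(h)
            feats.append(h)
        return feats


class LKDADecoder(nn.Module):
    def __init__(self, cfg: LKDANetConfig, *, rng: np.random.Generator):
        super().__init__()
        ch = cfg.stage_channels
        self.deep_supervision = cfg.deep_supervision
        self.ups = nn.ModuleList(
            UpsampleBlock(ch[i + 1], ch[i], rng=rng) for i in range(3, -1, -1))
        self.fusions = nn.ModuleList(
            SkipFusion(ch[i], rng=rng) for i in range(3, -1, -1))
        self.final_up = UpsampleBlock(ch[0], ch[0], rng=rng)
        self.head = nn.Conv3d(ch[0], cfg.num_classes, 1, rng=rng)
        if cfg.deep_supervision:
            # one independent pointwise head per fused scale (1/16 … 1/2)
            self.aux_heads = nn.ModuleList(
                nn.Conv3d(ch[i], cfg.num_classes, 1, rng=rng)
                for i in range(3, -1, -1))

    def forward(self, feats: list[Tensor]) -> tuple[Tensor, list[Tensor]]:
        if len(feats) != 5:
            raise ValueError(f"decoder expects 5 encoder features, "
                             f"got {len(feats)}")
        h = feats[4]
        aux: list[Tensor] = []
        for step, (up, fuse) in enumerate(zip(self.ups, self.fusions)):
            h = fuse(feats[3 - step], up(h))
            if self.deep_supervision:
                aux.append(self.aux_heads[step](h))
        logits = self.head(self.final_up(h))
        aux.reverse()  # finest (1/2) first
        return logits, aux


class LKDANet(nn.Module):
    """The assembled segmentation network.

    Deterministic construction: the same (config, seed) pair always yields
    bit-identical parameters.
    """

    def __init__(self, cfg: LKDANetConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = LKDAEncoder(cfg, rng=rng)
        self.decoder = LKDADecoder(cfg, rng=rng)

    def forward(self, x: Tensor, return_aux: bool = False):
        logits, aux = self.decoder(self.encoder(x))
        if return_aux:
            return logits, aux
        return logits

    def predict_proba(self, x: Tensor) -> np.ndarray:
        """Channel softmax of the logits as a plain array (no tape)."""
        logits = self.forward(nn.Tensor(x.data if isinstance(x, Tensor) else x))
        return F.softmax(logits, axis=1).data


# ---------------------------------------------------------------------------
# parameter counting


def count_parameters(cfg: LKDANetConfig, seed: int = 0) -> int:
    """Exact learnable-scalar count of the instantiated model."""
    return LKDANet(cfg, seed=seed).num_parameters()


def _block_param_count(cfg: LKDANetConfig, C: int) -> int:
    half = C // 2
    k1 = cfg.branch1[0] ** 3
    k2 = cfg.branch2[0] ** 3
    hidden = max(half // cfg.se_reduction, 1)
    attn = (C * half + half                # projection C -> C/2
            + half * (k1 + 1)              # depthwise branch 1
            + half * (k2 + 1)              # depthwise branch 2
            + cfg.mix_kernel ** 3 * 4 + 2  # dense 2 -> 2 mixing conv
            + half * hidden + hidden       # SE bottleneck down
            + hidden * half + half         # SE bottleneck up
            + half * C + C)                # output projection C/2 -> C
    dwca = (3 * cfg.dwca_expansion + 1) * C
    norms = 4 * C
    return attn + dwca + norms


def count_parameters_closed_form(cfg: LKDANetConfig) -> int:
    """Config-based closed-form parameter count (no instantiation).

    Cross-checks :func:`count_parameters`; the two must agree exactly.
    """
    ch = cfg.stage_channels
    K = cfg.num_classes
    total = cfg.patch_kernel ** 3 * cfg.in_channels * ch[0] + ch[0]
    for i in range(4):
        total += cfg.down_kernel ** 3 * ch[i] * ch[i + 1] + ch[i + 1]
        total += cfg.stage_depths[i] * _block_param_count(cfg, ch[i + 1])
    # decoder: four upsample blocks, four fusions, final upsample + head
    for i in range(4):
        cin, cout = ch[i + 1], ch[i]
        total += 27 * cin * cout + cout + 2 * cout          # conv + BN
        C = cout
        total += 2 * (27 * C * C + C + 2 * C)               # two fusion paths
        total += 2 * C * 4 * C + 4 * C + 8 * C              # pw 2C -> 4C + BN
        total += 4 * C * C + C + 2 * C                      # pw 4C -> C + BN
    total += 27 * ch[0] * ch[0] + ch[0] + 2 * ch[0]         # final upsample
    total += ch[0] * K + K                                  # head
    if cfg.deep_supervision:
        for i in range(4):
            total += ch[i] * K + K
    return total


# ---------------------------------------------------------------------------
# inspection and inference


def stage_shape_table(cfg: LKDANetConfig, input_size) -> list[dict]:
    """Analytic per-stage output shapes for a given input size."""
    size = tuple(int(s) for s in (input_size if hasattr(input_size, "__len__")
                                  else (input_size,) * 3))
    rows = []
    for i, c in enumerate(cfg.stage_channels):
        scale = 2 ** (i + 1)
        rows.append({"stage": i + 1, "scale": f"1/{scale}", "channels": c,
                     "shape": tuple(s // scale for s in size)})
    return rows


def model_info(cfg: LKDANetConfig, input_size=96) -> dict:
    n = count_parameters_closed_form(cfg)
    return {
        "parameters": n,
        "parameters_millions": round(n / 1e6, 2),
        "effective_receptive_field": effective_receptive_field(
            [cfg.branch1, cfg.branch2]),
        "stages": stage_shape_table(cfg, input_size),
    }


def _gaussian_importance(window: tuple[int, int, int]) -> np.ndarray:
    """Separable Gaussian window weight (sigma = extent/8), peak 1."""
    ws = []
    for n in window:
        x = np.arange(n) - (n - 1) / 2.0
        sigma = max(n / 8.0, 1.0)
        ws.append(np.exp(-0.5 * (x / sigma) ** 2))
    w = ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]
    return np.maximum(w, 1e-6)


def sliding_window_predict(model: LKDANet, image: np.ndarray, *,
                           window=96, overlap: float = 0.5) -> np.ndarray:
    """Segment an arbitrary-size volume by Gaussian-blended tiling.

    The image (D, H, W) is zero-padded so every axis fits at least one
    window; overlapping windows are predicted in eval mode, their softmax
    maps blended with a Gaussian importance weight, and the argmax labels
    cropped back to the input extent.
    """
    if image.ndim != 3:
        raise ValueError(f"expected a 3-D image, got rank {image.ndim}")
    win = tuple(int(w) for w in (window if hasattr(window, "__len__")
                                 else (window,) * 3))
    if any(w % 32 for w in win):
        raise ValueError(f"window dims must be divisible by 32, got {win}")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    shape = image.shape
    padded_shape = tuple(max(s, w) for s, w in zip(shape, win))
    pad = [(0, p - s) for s, p in zip(shape, padded_shape)]
    vol = np.pad(image.astype(np.float64), pad)

    steps = []
    for size, w in zip(padded_shape, win):
        stride = max(int(round(w * (1.0 - overlap))), 1)
        starts = list(range(0, max(size - w, 0) + 1, stride))
        if starts[-1] != size - w:
            starts.append(size - w)
        steps.append(sorted(set(starts)))

    K = model.cfg.num_classes
    acc = np.zeros((K, *padded_shape))
    weight = np.zeros(padded_shape)
    gauss = _gaussian_importance(win)
    was_training = model.training
    model.eval()
    try:
        for d0 in steps[0]:
            for h0 in steps[1]:
                for w0 in steps[2]:
                    tile = vol[d0:d0 + win[0], h0:h0 + win[1], w0:w0 + win[2]]
                    probs = model.predict_proba(
                        nn.Tensor(tile[None, None]))[0]
                    sl = (slice(d0, d0 + win[0]), slice(h0, h0 + win[1]),
                          slice(w0, w0 + win[2]))
                    acc[(slice(None),) + sl] += probs * gauss
                    weight[sl] += gauss
    finally:
        model.train(was_training)
    acc /= weight
    labels = acc.argmax(axis=0).astype(np.int64)
    return labels[:shape[0], :shape[1], :shape[2]]
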