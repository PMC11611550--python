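"""Self-Similarity-aware Attention Block (SSAB).

Three attention units act in parallel on an encoder feature map and their
outputs are summed and fused by a channel-preserving convolution:

* a **similarity attention unit**, gating the feature map with a sigmoid map
  built from the pixel-wise self-structural-similarity score
  ``score = (2 m + c2) / (2 m^2 + c2)`` where ``m`` is a sliding-window (box)
  local mean of the features and ``c2 = (k2 L)^2`` stabilises the weak
  denominator (``k2 = 0.03``, ``L`` the feature dynamic range);
* a **self-attention unit** in the SAGAN style: 1x1x1 query/key/value
  projections, row-softmax over flattened spatial positions, and a learnable
  residual scale ``gamma`` initialised to zero (so the unit starts as the
  identity);
* a **channel -> spatial convolutional attention** pair (CBAM ordering):
  pooled-channel descriptors through a shared MLP gate the channels, then a
  7-wide convolution over the channel mean/max maps gates positions.

All units are shape-preserving and every attention multiplier is a sigmoid,
hence strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grad import Tensor, concat, conv3d, softmax
from .nn import Conv3d, Linear, Module, Parameter


@dataclass
class SSABConfig:
    window_size: int | None = None      # None: max(3, nearest odd to min(spatial)/8)
    k2: float = 0.03
    dynamic_range_policy: str = "per-channel"  # or "fixed"
    fixed_range: float = 2.0            # used when policy == "fixed" ([-1,1] data)
    fusion_kernel: int = 1
    sa_reduction: int = 8
    ca_reduction: int = 16
    spatial_kernel: int = 7
    canonical_sssim: bool = False       # SSIM-style denominator variant
    attention_budget: int = 4096        # max spatial positions for self-attention

    def __post_init__(self):
        for k in (self.fusion_kernel, self.spatial_kernel):
            if k % 2 != 1:
                raise ValueError("kernels must be odd")
        if self.window_size is not None and (self.window_size < 3 or self.window_size % 2 != 1):
            raise ValueError("window_size must be an odd integer >= 3")
        if self.sa_reduction < 1 or self.ca_reduction < 1:
            raise ValueError("reductions must be >= 1")


def _auto_window(spatial: tuple[int, ...]) -> int:
    w = int(round(min(spatial) / 8.0))
    w = max(3, w)
    if w % 2 == 0:
        w += 1
    return w


def self_similarity_map(f: Tensor, cfg: SSABConfig) -> Tensor:
    """Per-channel self-similarity score map (same shape as the input).

    ``f`` is NCDHW.  The local mean is a box filter of ``window_size``; the
    dynamic range L is the per-channel max-min of the features (clamped below
    at 1e-3) or a fixed constant, and is treated as a constant w.r.t.
    gradients.
    """
    spatial = f.shape[2:]
    win = cfg.window_size or _auto_window(spatial)
    if any(s < win for s in spatial):
        raise ValueError(f"window {win} larger than spatial grid {spatial}")
    c = f.shape[1]
    box = Tensor(np.zeros((c, c, win, win, win), dtype=f.data.dtype))
    val = 1.0 / win**3
    for ch in range(c):
        box.data[ch, ch] = val
    m = conv3d(f, box, stride=1, padding=win // 2)

    if cfg.dynamic_range_policy == "fixed":
        big_l = np.full((1, c, 1, 1, 1), cfg.fixed_range, dtype=f.data.dtype)
    else:
        flat = f.data.reshape(f.shape[0], c, -1)
        rng = flat.max(axis=2) - flat.min(axis=2)
        big_l = np.maximum(rng, 1e-3).reshape(f.shape[0], c, 1, 1, 1)
    c2 = Tensor((cfg.k2 * big_l) ** 2)

    if cfg.canonical_sssim:
        # SSIM-style structure term comparing features to their local mean
        return (2.0 * m * f + c2) / (m * m + f * f + c2)
    return (2.0 * m + c2) / (2.0 * m * m + c2)


class SimilarityAttention(Module):
    """sigmoid(Conv7(score map) + Conv7(F)) broadcast over channels, times F."""

    def __init__(self, channels: int, cfg: SSABConfig, rng: np.random.Generator):
        self.cfg = cfg
        k = cfg.spatial_kernel
        self.conv_score = Conv3d(channels, 1, k, rng=rng)
        self.conv_feat = Conv3d(channels, 1, k, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        score = self_similarity_map(f, self.cfg)
        a = (self.conv_score(score) + self.conv_feat(f)).sigmoid()
        return a * f

    def attention_map(self, f: Tensor) -> np.ndarray:
        score = self_similarity_map(f, self.cfg)
        return (self.conv_score(score) + self.conv_feat(f)).sigmoid().data


class SelfAttention(Module):
    """SAGAN-style spatial self-attention with zero-initialised residual gain."""

    def __init__(self, channels: int, cfg: SSABConfig, rng: np.random.Generator):
        if channels < cfg.sa_reduction:
            raise ValueError("channels must be >= sa_reduction")
        self.cfg = cfg
        inner = max(1, channels // cfg.sa_reduction)
        self.query = Conv3d(channels, inner, 1, rng=rng)
        self.key = Conv3d(channels, inner, 1, rng=rng)
        self.value = Conv3d(channels, channels, 1, rng=rng)
        self.gamma = Parameter(np.zeros(1))

    def forward(self, f: Tensor) -> Tensor:
        n, c = f.shape[:2]
        spatial = f.shape[2:]
        npos = int(np.prod(spatial))
        if npos > self.cfg.attention_budget:
            raise ValueError(
                f"self-attention over {npos} positions exceeds the budget "
                f"({self.cfg.attention_budget}); place the block at a deeper, "
                "downsampled encoder level")
        q = self.query(f).reshape(n, -1, npos)          # (n, ci, L)
        k = self.key(f).reshape(n, -1, npos)
        v = self.value(f).reshape(n, c, npos)
        scores = q.transpose(0, 2, 1) @ k               # (n, L, L)
        attn = softmax(scores, axis=-1)                 # rows sum to 1
        out = v @ attn.transpose(0, 2, 1)               # (n, c, L)
        out = out.reshape(n, c, *spatial)
        return self.gamma * out + f


class CBAMAttention(Module):
    """Channel attention followed by spatial attention (that order)."""

    def __init__(self, channels: int, cfg: SSABConfig, rng: np.random.Generator):
        if channels < cfg.ca_reduction:
            raise ValueError("channels must be >= ca_reduction")
        hidden = max(1, channels // cfg.ca_reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.spatial_conv = Conv3d(2, 1, cfg.spatial_kernel, rng=rng)

    def _mlp(self, pooled: Tensor) -> Tensor:
        return self.fc2(self.fc1(pooled).relu())

    def forward(self, f: Tensor) -> Tensor:
        ca, f_scaled, sa = self._stages(f)
        return sa * f_scaled

    def _stages(self, f: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        n, c = f.shape[:2]
        avg = f.mean(axis=(2, 3, 4))                    # (n, c)
        mx = f.max(axis=(2, 3, 4))
        ca = (self._mlp(avg) + self._mlp(mx)).sigmoid().reshape(n, c, 1, 1, 1)
        f_scaled = ca * f
        ch_mean = f_scaled.mean(axis=1, keepdims=True)
        ch_max = f_scaled.max(axis=1, keepdims=True)
        sa = self.spatial_conv(concat([ch_mean, ch_max], axis=1)).sigmoid()
        return ca, f_scaled, sa

    def attention_maps(self, f: Tensor) -> tuple[np.ndarray, np.ndarray]:
        """(channel multipliers, spatial multiplier map) for inspection."""
        ca, _, sa = self._stages(f)
        return ca.data, sa.data


class SSABBlock(Module):
    """Sum of the three attention unit outputs, fused by a 1x1x1 convolution."""

    def __init__(self, channels: int, cfg: SSABConfig | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg or SSABConfig()
        self.self_attn = SelfAttention(channels, self.cfg, rng)
        self.sim_attn = SimilarityAttention(channels, self.cfg, rng)
        self.cbam = CBAMAttention(channels, self.cfg, rng)
        self.fusion = Conv3d(channels, channels, self.cfg.fusion_kernel, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        return self.fusion(self.self_attn(f) + self.sim_attn(f) + self.cbam(f))


def build_attention(kind: str, channels: int, cfg: SSABConfig,
                    rng: np.random.Generator) -> Module | None:
    """Attention factory used by the generator's ablation axis."""
    kind = (kind or "none").lower()
    if kind == "none":
        return None
    if kind == "ssab":
        return SSABBlock(channels, cfg, rng)
    if kind in ("self", "self_attention"):
        return SelfAttention(channels, cfg, rng)
    if kind in ("similarity", "similarity_attention"):
        return SimilarityAttention(channels, cfg, rng)
    if kind == "cbam":
        return CBAMAttention(channels, cfg, rng)
    raise ValueError(f"unknown attention type {kind!r}")
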