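"""Conditional generator and patch discriminator for volumetric denoising.

The generator is a pix2pix-lineage 3D U-Net: a large-kernel (default 7^3)
input convolution, a strided-convolution encoder with SSAB attention applied
to the feature maps of selected encoder levels, and a nearest-neighbour
upsample + convolution decoder with skip connections, ending in tanh so the
output lives in [-1, 1] like the preprocessed inputs.

The discriminator is a 3D patch discriminator: a stack of stride-2
convolutions producing a per-patch logit map (no final sigmoid; the losses
apply it).  In conditional mode it sees the low-count input concatenated with
the candidate on the channel axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grad import Tensor, concat
from .nn import Conv3d, ConvTranspose3d, Module
from .ssab import SSABConfig, build_attention


@dataclass
class GeneratorSpec:
    levels: int = 4
    base_channels: int = 32
    input_kernel: int | None = 7       # None removes the large input convolution
    ssab_positions: frozenset[int] = field(default_factory=lambda: frozenset({2, 3}))
    attention_type: str = "ssab"
    ssab: SSABConfig = field(default_factory=SSABConfig)
    seed: int = 0

    def __post_init__(self):
        self.ssab_positions = frozenset(self.ssab_positions)
        bad = [p for p in self.ssab_positions if not (1 <= p <= self.levels)]
        if bad:
            raise ValueError(f"ssab_positions {bad} outside encoder levels 1..{self.levels}")


@dataclass
class DiscriminatorSpec:
    layers: int = 3
    base_channels: int = 32
    conditional: bool = True
    enabled: bool = True
    seed: int = 0


class Generator(Module):
    def __init__(self, spec: GeneratorSpec | None = None):
        self.spec = spec or GeneratorSpec()
        s = self.spec
        rng = np.random.default_rng(s.seed)
        b = s.base_channels

        self.stem = (Conv3d(1, b, s.input_kernel, rng=rng)
                     if s.input_kernel is not None else None)
        self.enc: list[Conv3d] = []
        self.attn: list[Module | None] = []
        ch = b if self.stem is not None else 1
        self.enc_channels = [ch]
        for lvl in range(1, s.levels + 1):
            out_ch = b * 2**lvl
            self.enc.append(Conv3d(ch, out_ch, 4, stride=2, padding=1, rng=rng))
            att = None
            if lvl in s.ssab_positions and s.attention_type != "none":
                att = build_attention(s.attention_type, out_ch, s.ssab, rng)
            self.attn.append(att)
            ch = out_ch
            self.enc_channels.append(ch)

        # decoder: transposed convs with skip concatenation, then a 1x1x1 head
        # fusing the full-resolution stem features
        self.dec: list[ConvTranspose3d] = []
        for lvl in range(s.levels, 0, -1):
            in_ch = ch if lvl == s.levels else ch + self.enc_channels[lvl]
            out_ch = max(b, self.enc_channels[lvl - 1])
            self.dec.append(ConvTranspose3d(in_ch, out_ch, 4, stride=2, padding=1,
                                            rng=rng))
            ch = out_ch
        self.head = Conv3d(ch + self.enc_channels[0], 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = self.spec
        spatial = x.shape[2:]
        div = 2**s.levels
        bad = [d for d in spatial if d % div != 0]
        if bad:
            need = tuple((div - d % div) % div for d in spatial)
            raise ValueError(
                f"input spatial shape {spatial} not divisible by 2^{s.levels}; "
                f"pad by {need} voxels")
        h = self.stem(x).leaky_relu(0.2) if self.stem is not None else x
        skips = [h]
        for conv, att in zip(self.enc, self.attn):
            h = conv(h).leaky_relu(0.2)
            if att is not None:
                h = att(h)
            skips.append(h)
        for i, tconv in enumerate(self.dec):
            if i > 0:
                h = concat([h, skips[self.spec.levels - i]], axis=1)
            h = tconv(h).leaky_relu(0.2)
        return self.head(concat([h, skips[0]], axis=1)).tanh()

    def denoise(self, volume: np.ndarray) -> np.ndarray:
        """Inference on a single preprocessed (D, H, W) array."""
        x = Tensor(np.asarray(volume, dtype=np.float32)[None, None])
        return self.forward(x).data[0, 0]

    def attention_maps(self, volume: np.ndarray) -> dict[int, np.ndarray]:
        """Sigmoid similarity-attention maps per SSAB level, for inspection."""
        x = Tensor(np.asarray(volume, dtype=np.float32)[None, None])
        h = self.stem(x).leaky_relu(0.2) if self.stem is not None else x
        maps: dict[int, np.ndarray] = {}
        for lvl, (conv, att) in enumerate(zip(self.enc, self.attn), start=1):
            h = conv(h).leaky_relu(0.2)
            if att is not None:
                if hasattr(att, "sim_attn"):
                    maps[lvl] = att.sim_attn.attention_map(h)[0, 0]
                elif hasattr(att, "attention_map"):
                    maps[lvl] = att.attention_map(h)[0, 0]
                h = att(h)
        return maps


class Discriminator(Module):
    def __init__(self, spec: DiscriminatorSpec | None = None):
        self.spec = spec or DiscriminatorSpec()
        s = self.spec
        rng = np.random.default_rng(s.seed + 1000)
        in_ch = 2 if s.conditional else 1
        self.convs: list[Conv3d] = []
        ch = in_ch
        for i in range(s.layers):
            out_ch = s.base_channels * 2**i
            self.convs.append(Conv3d(ch, out_ch, 4, stride=2, padding=1, rng=rng))
            ch = out_ch
        self.head = Conv3d(ch, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, ld: Tensor | np.ndarray, candidate: Tensor | np.ndarray) -> Tensor:
        if not isinstance(candidate, Tensor):
            candidate = Tensor(np.asarray(candidate, dtype=np.float32))
        if not isinstance(ld, Tensor):
            ld = Tensor(np.asarray(ld, dtype=np.float32))
        if ld.shape != candidate.shape:
            raise ValueError(f"shape mismatch: {ld.shape} vs {candidate.shape}")
        h = concat([ld, candidate], axis=1) if self.spec.conditional else candidate
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        return self.head(h)  # per-patch logits
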