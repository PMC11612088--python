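"""Segmentation architectures for small bright objects on CT.

Two families, both rank-agnostic (2D slices, 15-channel 2.5D stacks, or 3D
patches):

* ``AttentionalUNet`` — classic encoder/decoder with 4 pooling stages (16x
  total down-sampling) and attention-gated skip fusion.  The gate projects
  decoder and encoder features to a shared low-dimensional space, forms a
  1-channel sigmoid map H and rescales the encoder feature with it before
  concatenation.

* ``SNet`` (spatial context network) — only 2 pooling stages (4x total
  down-sampling) to keep small objects alive in the feature map, a dense
  atrous spatial pyramid (dilations 3, 6, 9, 12 with forward concatenation)
  to recover receptive field without further down-sampling, and reverse
  axial attention in both decoder levels: factorised 1D self-attention over
  the encoder skip, gated by 1 - sigmoid(decoder heatmap) so attention mass
  flows to regions the decoder is not yet confident about.  Each decoder
  level also emits a partial heatmap that is upsampled to input resolution
  and supervised directly.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .nn import (AdamW, BatchNorm, Conv, ConvBlock, ConvTranspose2x, Linear,
                 Module, Tensor, astensor, concat, maxpool2, softmax,
                 upsample_nearest)

__all__ = ["SegOutputs", "AttentionGate", "AttentionalUNet", "AxialAttention",
           "DenseASPP", "ReverseAxialAttention", "SNet", "build_model"]


@dataclasses.dataclass
class SegOutputs:
    """Outputs of a segmentation forward pass.

    ``final_prob`` is the per-pixel foreground probability at input
    resolution; ``partial_heatmaps`` are per-decoder-level pre-sigmoid
    logits already upsampled to input resolution (empty for the U-Net);
    the head outputs are optional.
    """

    final_prob: Tensor
    partial_heatmaps: list = dataclasses.field(default_factory=list)
    class_logit: Tensor | None = None
    loc_heatmap: Tensor | None = None


def _check_divisible(shape, multiple: int, arch: str):
    if any(s % multiple for s in shape):
        raise ValueError(
            f"{arch} requires spatial dims divisible by {multiple}, got {tuple(shape)}")


class AttentionGate(Module):
    """Additive attention gate fusing a decoder feature with an encoder skip.

    H = sigmoid(psi(relu(W_g x_d + W_s x_e))) is a single-channel gate;
    the gated encoder feature H * x_e is concatenated with x_d and fused by
    a 3x3 convolution.
    """

    def __init__(self, ndim: int, c_d: int, c_e: int, p: int,
                 rng: np.random.Generator | None = None):
        if p >= max(c_d, c_e):
            raise ValueError(f"projection dim P={p} must be smaller than C={max(c_d, c_e)}")
        self.w_g = Conv(ndim, c_d, p, k=1, rng=rng)
        self.w_s = Conv(ndim, c_e, p, k=1, rng=rng)
        self.psi = Conv(ndim, p, 1, k=1, rng=rng)
        self.fuse = ConvBlock(ndim, c_e + c_d, c_d, k=3, rng=rng)

    def forward(self, x_d, x_e, return_gate: bool = False):
        h = self.psi((self.w_g(x_d) + self.w_s(x_e)).relu()).sigmoid()
        out_f = h * x_e
        x = self.fuse(concat([out_f, x_d], axis=1))
        return (x, h) if return_gate else x


class AttentionalUNet(Module):
    """U-Net with 4 pooling stages and attention-gated skip connections.

    The bottleneck sits at 1/16 of the input resolution; three transposed-
    convolution decoder stages with gated fusion bring the feature back to
    1/2, and a final 2x upsampling + 1x1 convolution restores input
    resolution for the probability map.
    """

    downsampling_factor = 16

    def __init__(self, ndim: int = 2, in_channels: int = 1, base: int = 32,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        b = base
        self.ndim = ndim
        self.enc = [
            [ConvBlock(ndim, in_channels, b, rng=rng), ConvBlock(ndim, b, b, rng=rng)],
            [ConvBlock(ndim, b, 2 * b, rng=rng), ConvBlock(ndim, 2 * b, 2 * b, rng=rng)],
            [ConvBlock(ndim, 2 * b, 4 * b, rng=rng), ConvBlock(ndim, 4 * b, 4 * b, rng=rng)],
            [ConvBlock(ndim, 4 * b, 8 * b, rng=rng), ConvBlock(ndim, 8 * b, 8 * b, rng=rng)],
        ]
        self.bottleneck = ConvBlock(ndim, 8 * b, 16 * b, rng=rng)
        self.up = [ConvTranspose2x(ndim, 16 * b, 8 * b, rng=rng),
                   ConvTranspose2x(ndim, 8 * b, 4 * b, rng=rng),
                   ConvTranspose2x(ndim, 4 * b, 2 * b, rng=rng)]
        self.gates = [AttentionGate(ndim, 8 * b, 8 * b, 4 * b, rng=rng),
                      AttentionGate(ndim, 4 * b, 4 * b, 2 * b, rng=rng),
                      AttentionGate(ndim, 2 * b, 2 * b, b, rng=rng)]
        self.head = Conv(ndim, 2 * b, 1, k=1, rng=rng)
        # background-prior init: start near-empty predictions so the first
        # epochs are not dominated by false-positive gradient on empty slices
        self.head.bias.data[:] = -2.0

    def bottleneck_shape(self, spatial) -> tuple:
        return tuple(s // self.downsampling_factor for s in spatial)

    def encode(self, x):
        """Encoder pass; returns (skip features, bottleneck feature)."""
        x = astensor(x)
        _check_divisible(x.shape[2:], self.downsampling_factor, "AttentionalUNet")
        skips = []
        for stage in self.enc:
            for block in stage:
                x = block(x)
            skips.append(x)
            x = maxpool2(x)
        return skips, self.bottleneck(x)

    def forward(self, x) -> SegOutputs:
        skips, x = self.encode(x)
        for up, gate, skip in zip(self.up, self.gates, reversed(skips[1:])):
            x = gate(up(x), skip)
        prob = self.head(upsample_nearest(x, 2)).sigmoid()
        return SegOutputs(final_prob=prob, partial_heatmaps=[])


class AxialAttention(Module):
    """Self-attention factorised into 1D passes along each spatial axis.

    Along each axis, every 1D fibre attends within itself:
    A = softmax(Q K^T / sqrt(d_k)), output = A V, with Q/K/V from 1x1
    convolutions on the input.  Single head; d_k = max(channels // 8, 8).
    """

    def __init__(self, ndim: int, channels: int,
                 rng: np.random.Generator | None = None):
        self.ndim = ndim
        self.d_k = max(channels // 8, 8)
        self.q_convs = [Conv(ndim, channels, self.d_k, k=1, rng=rng) for _ in range(ndim)]
        self.k_convs = [Conv(ndim, channels, self.d_k, k=1, rng=rng) for _ in range(ndim)]
        self.v_convs = [Conv(ndim, channels, channels, k=1, rng=rng) for _ in range(ndim)]

    @staticmethod
    def _attend_axis(q, k, v, axis: int, collect=None):
        """Attention along one spatial axis of (N, C, *S) tensors."""
        # move the attended axis last, flatten everything else into batch
        nd = q.ndim
        perm = [i for i in range(nd) if i != axis] + [axis]
        L = q.shape[axis]
        dk = q.shape[1]
        c = v.shape[1]
        qt = q.transpose(perm)            # (N, dk, *rest, L)
        kt = k.transpose(perm)
        vt = v.transpose(perm)            # (N, C, *rest, L)
        rest = int(np.prod(qt.shape[2:-1])) if nd > 3 else 1
        qm = qt.reshape(qt.shape[0], dk, rest, L).transpose((0, 2, 3, 1))  # (N, rest, L, dk)
        km = kt.reshape(kt.shape[0], dk, rest, L).transpose((0, 2, 3, 1))
        vm = vt.reshape(vt.shape[0], c, rest, L).transpose((0, 2, 3, 1))   # (N, rest, L, C)
        a = softmax((qm @ km.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk)), axis=-1)
        if collect is not None:
            collect.append(a.data)
        out = a @ vm                                                        # (N, rest, L, C)
        out = out.transpose((0, 3, 1, 2)).reshape(vt.shape)
        inv = list(np.argsort(perm))
        return out.transpose(inv)

    def forward(self, e, return_weights: bool = False):
        x = e
        weights = [] if return_weights else None
        for i in range(self.ndim):
            axis = 2 + i
            q, k, v = self.q_convs[i](x), self.k_convs[i](x), self.v_convs[i](x)
            x = self._attend_axis(q, k, v, axis, collect=weights)
        return (x, weights) if return_weights else x


class DenseASPP(Module):
    """Dense atrous spatial pyramid: dilated 3x3 stages with forward concatenation.

    Stage k convolves the running concatenation of the input with all
    previous stage outputs, so the input channel count grows by ``growth``
    per stage; a final 1x1 convolution reduces to ``c_out``.  Spatial shape
    is preserved exactly (padding = dilation).
    """

    def __init__(self, ndim: int, c_in: int, growth: int, c_out: int,
                 dilations=(3, 6, 9, 12), rng: np.random.Generator | None = None):
        dilations = tuple(dilations)
        if len(dilations) != 4:
            raise ValueError(f"dense ASPP expects exactly 4 dilation rates, got {dilations}")
        if any(d <= 0 for d in dilations):
            raise ValueError(f"dilations must be positive, got {dilations}")
        self.dilations = dilations
        self.stage_input_channels = [c_in + i * growth for i in range(4)]
        self.stages = [ConvBlock(ndim, self.stage_input_channels[i], growth,
                                 k=3, dilation=d, rng=rng)
                       for i, d in enumerate(dilations)]
        self.reduce = ConvBlock(ndim, c_in + 4 * growth, c_out, k=1, rng=rng)

    def forward(self, e4):
        running = astensor(e4)
        for stage in self.stages:
            p = stage(running)
            running = concat([p, running], axis=1)
        return self.reduce(running)


class ReverseAxialAttention(Module):
    """Decoder-level module: axial attention on the skip, reverse-gated.

    gate = 1 - sigmoid(conv1x1(decoder feature)) suppresses regions the
    decoder already marks as foreground, so the attended encoder feature
    concentrates on residual (missed) structure.  Emits the filtered
    feature, a 1-channel supervision heatmap, and the fused level output.
    """

    def __init__(self, ndim: int, c_e: int, c_d: int, c_out: int,
                 rng: np.random.Generator | None = None):
        self.attention = AxialAttention(ndim, c_e, rng=rng)
        self.gate_conv = Conv(ndim, c_d, 1, k=1, rng=rng)
        self.heat_conv = Conv(ndim, c_e, 1, k=1, rng=rng)
        self.fuse = ConvBlock(ndim, c_e + c_d, c_out, k=3, rng=rng)

    def forward(self, d_level, e_level, return_gate: bool = False):
        if d_level.shape[2:] != e_level.shape[2:]:
            raise ValueError(
                f"decoder/encoder spatial mismatch {d_level.shape[2:]} vs {e_level.shape[2:]}")
        gate = 1.0 - self.gate_conv(d_level).sigmoid()
        filtered = gate * self.attention(e_level)
        heatmap = self.heat_conv(filtered)
        fused = self.fuse(concat([filtered, d_level], axis=1))
        if return_gate:
            return fused, heatmap, gate
        return fused, heatmap


class SNet(Module):
    """Spatial context network: shallow encoder, dense ASPP, RAA decoder."""

    downsampling_factor = 4

    def __init__(self, ndim: int = 2, in_channels: int = 1, base: int = 32,
                 dilations=(3, 6, 9, 12), with_heads: bool = False, seed: int = 0):
        rng = np.random.default_rng(seed)
        b = base
        self.ndim = ndim
        self.enc1 = [ConvBlock(ndim, in_channels, b, rng=rng),
                     ConvBlock(ndim, b, b, rng=rng)]
        self.enc2 = [ConvBlock(ndim, b, 2 * b, rng=rng),
                     ConvBlock(ndim, 2 * b, 2 * b, rng=rng)]
        self.depth = [ConvBlock(ndim, 2 * b, 4 * b, rng=rng),
                      ConvBlock(ndim, 4 * b, 4 * b, rng=rng)]
        self.aspp = DenseASPP(ndim, 4 * b, b, 2 * b, dilations=dilations, rng=rng)
        self.up2 = ConvTranspose2x(ndim, 2 * b, 2 * b, rng=rng)
        self.raa2 = ReverseAxialAttention(ndim, 2 * b, 2 * b, 2 * b, rng=rng)
        self.reduce1 = Conv(ndim, 2 * b, b, k=1, rng=rng)
        self.up1 = ConvTranspose2x(ndim, b, b, rng=rng)
        self.raa1 = ReverseAxialAttention(ndim, b, b, b, rng=rng)
        self.head = Conv(ndim, b, 1, k=1, rng=rng)
        # background-prior init, as in the U-Net head
        self.head.bias.data[:] = -2.0
        self.with_heads = with_heads
        if with_heads:
            self.class_head = Linear(4 * b, 1, rng=rng)
            self.loc_head = Conv(ndim, 2 * b, 1, k=1, rng=rng)

    def encode(self, x):
        x = astensor(x)
        _check_divisible(x.shape[2:], self.downsampling_factor, "SNet")
        for block in self.enc1:
            x = block(x)
        e1 = x
        x = maxpool2(x)
        for block in self.enc2:
            x = block(x)
        e2 = x
        x = maxpool2(x)
        for block in self.depth:
            x = block(x)
        return e1, e2, x

    def forward(self, x, with_heads: bool | None = None) -> SegOutputs:
        use_heads = self.with_heads if with_heads is None else (with_heads and self.with_heads)
        e1, e2, e4 = self.encode(x)
        f_m = self.aspp(e4)
        d2 = self.up2(f_m)
        x2, heat2 = self.raa2(d2, e2)
        d1 = self.up1(self.reduce1(x2))
        x1, heat1 = self.raa1(d1, e1)
        prob = self.head(x1).sigmoid()
        heatmaps = [upsample_nearest(heat2, 2), heat1]
        out = SegOutputs(final_prob=prob, partial_heatmaps=heatmaps)
        if use_heads:
            pooled = e4.mean(axis=tuple(range(2, e4.ndim)))
            out.class_logit = self.class_head(pooled)
            out.loc_heatmap = self.loc_head(f_m)
        return out


def build_model(config: dict) -> Module:
    """Construct a network from a plain config dict.

    Keys: arch ('snet' | 'attention_unet'), ndim (2 or 3), in_channels
    (1 for 2D/3D, 15 for 2.5D), base, dilations, with_heads, seed.
    """
    cfg = dict(config)
    arch = cfg.pop("arch", "snet")
    if arch == "snet":
        return SNet(ndim=cfg.get("ndim", 2), in_channels=cfg.get("in_channels", 1),
                    base=cfg.get("base", 32), dilations=tuple(cfg.get("dilations", (3, 6, 9, 12))),
                    with_heads=cfg.get("with_heads", False), seed=cfg.get("seed", 0))
    if arch == "attention_unet":
        return AttentionalUNet(ndim=cfg.get("ndim", 2),
                               in_channels=cfg.get("in_channels", 1),
                               base=cfg.get("base", 32), seed=cfg.get("seed", 0))
    raise ValueError(f"unknown architecture {arch!r}")
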