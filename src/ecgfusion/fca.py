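"""Frequency channel attention (FCA) primitives.

FCA generalises squeeze-and-excitation: instead of summarising every
channel by its spatial mean, channels are split into groups and each group
is summarised by one 2-D DCT coefficient of its feature map,

    z_c = sum_{h,w} X[c, h, w] * B^{(u_g, v_g)}[h, w],
    B^{(u,v)}[h, w] = cos(pi*u*(h+1/2)/H) * cos(pi*v*(w+1/2)/W),

so the (0, 0) frequency recovers (H*W times) the global-average squeeze.
The descriptors pass through the usual two-layer bottleneck gate
sigma(W2 . relu(W1 . z)) and the resulting per-channel weights rescale the
feature map.  This module holds the numpy-level math; the trainable layer
lives in :mod:`ecgfusion.network`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["FcaConfig", "dct_basis", "select_frequencies", "spectral_descriptor",
           "fca_gate", "fca_forward"]


@dataclass
class FcaConfig:
    """Frequency pairs + bottleneck ratio defining one attention block.

    n_freq : number of frequency groups (must divide the channel count).
    reduction : bottleneck ratio r; the gate hidden width is C // r
        (at least 1).
    strategy : "lowest" picks the n pairs with smallest u+v (ties by u then
        v, starting at (0,0) - low-frequency dominance); "custom" uses
        ``custom_pairs`` verbatim after validation.
    """

    n_freq: int = 16
    reduction: int = 16
    strategy: str = "lowest"
    custom_pairs: list[tuple[int, int]] | None = None

    def pairs(self, height: int, width: int) -> list[tuple[int, int]]:
        if self.strategy == "custom":
            if not self.custom_pairs:
                raise ValueError("custom strategy requires custom_pairs")
            return select_frequencies(
                len(self.custom_pairs), height, width, "custom", self.custom_pairs
            )
        return select_frequencies(self.n_freq, height, width, self.strategy)


@lru_cache(maxsize=256)
def _cached_basis(height: int, width: int, u: int, v: int) -> np.ndarray:
    h = (np.arange(height) + 0.5) / height
    w = (np.arange(width) + 0.5) / width
    b = np.cos(np.pi * u * h)[:, None] * np.cos(np.pi * v * w)[None, :]
    b.setflags(write=False)
    return b


def dct_basis(height: int, width: int, u: int, v: int) -> np.ndarray:
    """Unnormalised 2-D DCT basis matrix for frequency pair (u, v).

    Cached per (H, W, u, v): repeated calls return bit-identical arrays.
    Normalisation constants are omitted - they would be absorbed by the
    gate's first linear layer anyway.
    """
    if not (0 <= u < height and 0 <= v < width):
        raise ValueError(f"frequency ({u}, {v}) out of range for {height}x{width}")
    return _cached_basis(height, width, u, v)


def select_frequencies(
    n: int,
    height: int,
    width: int,
    strategy: str = "lowest",
    custom_pairs: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Choose the n DCT frequency pairs used to summarise channel groups."""
    if n > height * width:
        raise ValueError(f"cannot select {n} pairs from a {height}x{width} grid")
    if strategy == "custom":
        pairs = [tuple(p) for p in (custom_pairs or [])]
        for u, v in pairs:
            if not (0 <= u < height and 0 <= v < width):
                raise ValueError(f"custom pair ({u}, {v}) out of range")
        return pairs
    if strategy != "lowest":
        raise ValueError(f"unknown strategy {strategy!r}")
    allp = [(u, v) for u in range(height) for v in range(width)]
    allp.sort(key=lambda p: (p[0] + p[1], p[0], p[1]))
    return allp[:n]


def basis_stack(height: int, width: int, pairs: list[tuple[int, int]]) -> np.ndarray:
    """(n, H, W) array of basis matrices, one per frequency pair."""
    return np.stack([dct_basis(height, width, u, v) for u, v in pairs])


def spectral_descriptor(x: np.ndarray, config: FcaConfig) -> np.ndarray:
    """Per-channel DCT descriptors of a (C, H, W) or (N, C, H, W) map.

    Channels are split into ``n_freq`` contiguous groups; every channel in
    group g is projected onto that group's basis matrix.
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    n_batch, c, h, w = x.shape
    pairs = config.pairs(h, w)
    n = len(pairs)
    if c % n:
        raise ValueError(f"channel count {c} not divisible by {n} frequency groups")
    per_channel = np.repeat(basis_stack(h, w, pairs), c // n, axis=0)  # (C, H, W)
    z = np.einsum("nchw,chw->nc", x, per_channel)
    return z[0] if squeeze else z


def fca_gate(z: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Bottleneck gate a = sigmoid(W2 . relu(W1 . z)); values in (0, 1)."""
    hidden = np.maximum(z @ w1.T, 0.0)
    return 1.0 / (1.0 + np.exp(-(hidden @ w2.T)))


def fca_forward(
    x: np.ndarray, w1: np.ndarray, w2: np.ndarray, config: FcaConfig
) -> np.ndarray:
    """Reference forward pass: descriptors -> gate -> channel re-weighting."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    z = spectral_descriptor(x, config)
    a = fca_gate(z, w1, w2)
    y = x * a[:, :, None, None]
    return y[0] if squeeze else y
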