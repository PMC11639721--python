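"""Time-series-to-image encodings: recurrence plot, Gramian angular field,
Markov transition field, and channel-wise fusion.

A beat of length L becomes three L x L images:

* **RP** - pairwise value recurrences, either thresholded (Heaviside of
  ``eps - |x_i - x_j|``) or the raw distance matrix.
* **GAF** - the series is min-max rescaled into the arccos domain, mapped
  to angles phi = arccos(x~), and imaged as cos(phi_i + phi_j) (summation
  field, GASF) or a difference field (GADF).
* **MTF** - values are quantile-binned, a first-order Markov transition
  matrix W between bins is estimated along time and row-normalised, and
  pixel (k, l) receives the transition probability between the bins of
  x_k and x_l.

The three channels are stacked in the fixed order (RP, GAF, MTF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalizedSeries",
    "TransitionMatrix",
    "BeatImageStack",
    "ImagingConfig",
    "normalize",
    "gasf",
    "gadf",
    "recurrence",
    "mtf",
    "fuse",
    "encode_beat",
]


@dataclass
class NormalizedSeries:
    values: np.ndarray
    range_mode: str  # "[-1,1]" or "[0,1]"


@dataclass
class TransitionMatrix:
    """Row-stochastic Q x Q first-order bin-transition matrix."""

    W: np.ndarray
    bin_edges: np.ndarray


@dataclass
class BeatImageStack:
    """Fused multi-channel square image encoding of one beat."""

    channels: np.ndarray  # (3, L, L) or (1, 3L, L)
    channel_names: list[str] = field(default_factory=lambda: ["RP", "GAF", "MTF"])

    @property
    def array(self) -> np.ndarray:
        return self.channels


@dataclass
class ImagingConfig:
    """Defaults for the fused encoding.

    rp_mode : "binary" thresholds pairwise distances at ``rp_epsilon`` (or,
        when None, at the 10th percentile of the beat's own pairwise
        distances - a common recurrence-plot convention); "distance" keeps
        raw distances.
    gaf_kind : which Gramian field feeds the fused stack ("gasf"/"gadf").
    gadf_variant : "paper" -> cos(phi_i - phi_j); "standard" -> sin form.
    mtf_bins : number of quantile bins Q.
    """

    rp_mode: str = "binary"
    rp_epsilon: float | None = None
    gaf_kind: str = "gasf"
    gadf_variant: str = "paper"
    gaf_range: str = "[-1,1]"
    mtf_bins: int = 8
    fuse_axis: str = "channel"


def normalize(x: np.ndarray, range_mode: str = "[-1,1]") -> NormalizedSeries:
    """Min-max rescale into [-1, 1] or [0, 1].

    A constant series has no range to rescale; it maps to all zeros (with a
    warning) rather than dividing 0/0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot normalize an empty series")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant series normalized to all zeros", stacklevel=2)
        return NormalizedSeries(np.zeros_like(x), range_mode)
    if range_mode == "[-1,1]":
        out = ((x - hi) + (x - lo)) / (hi - lo)
    elif range_mode == "[0,1]":
        out = (x - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")
    return NormalizedSeries(out, range_mode)


def _angles(xn: NormalizedSeries | np.ndarray) -> np.ndarray:
    v = xn.values if isinstance(xn, NormalizedSeries) else np.asarray(xn, float)
    if np.any(np.abs(v) > 1 + 1e-9):
        raise ValueError("normalized values outside the arccos domain [-1, 1]")
    return np.arccos(np.clip(v, -1.0, 1.0))


def gasf(xn: NormalizedSeries | np.ndarray) -> np.ndarray:
    """Gramian angular summation field cos(phi_i + phi_j)."""
    phi = _angles(xn)
    return np.cos(phi[:, None] + phi[None, :])


def gadf(xn: NormalizedSeries | np.ndarray, variant: str = "paper") -> np.ndarray:
    """Gramian angular difference field.

    variant "paper": cos(phi_i - phi_j) - symmetric with unit diagonal.
    variant "standard": sin(phi_i - phi_j) - the usual antisymmetric form.
    """
    phi = _angles(xn)
    d = phi[:, None] - phi[None, :]
    if variant == "paper":
        return np.cos(d)
    if variant == "standard":
        return np.sin(d)
    raise ValueError(f"unknown GADF variant {variant!r}")


def recurrence(
    x: np.ndarray,
    epsilon: float | None = None,
    mode: str = "binary",
) -> np.ndarray:
    """Recurrence plot of a scalar series.

    binary mode: entry (i, j) is 1 when |x_i - x_j| <= eps, else 0; when
    ``epsilon`` is None it defaults to the 10th percentile of the pairwise
    distances.  distance mode: the raw |x_i - x_j| matrix.
    """
    x = np.asarray(x, dtype=np.float64)
    dist = np.abs(x[:, None] - x[None, :])
    if mode == "distance":
        return dist
    if mode != "binary":
        raise ValueError(f"unknown recurrence mode {mode!r}")
    if epsilon is None:
        epsilon = float(np.percentile(dist, 10))
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0 in binary mode")
    return (dist <= epsilon).astype(np.float64)


def _quantile_bins(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign each value to a quantile bin; returns (assignments, edges).

    Duplicate quantile edges (few distinct values) are merged with a
    warning, so bins are always strictly increasing.
    """
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        warnings.warn(
            f"only {len(uniq) - 1} distinct quantile bins available "
            f"(requested {n_bins}); bins merged",
            stacklevel=3,
        )
        edges = uniq
    if len(edges) < 2:  # constant series: one degenerate bin
        edges = np.array([x[0], x[0]])
        return np.zeros(len(x), dtype=np.intp), edges
    # interior edges are cut points; bins are left-closed (ties go up)
    assign = np.searchsorted(edges[1:-1], x, side="right")
    return assign.astype(np.intp), edges


def mtf(x: np.ndarray, n_bins: int = 8) -> tuple[np.ndarray, TransitionMatrix]:
    """Markov transition field and its underlying transition matrix.

    W[i, j] is the probability that a value in bin i is immediately
    followed by a value in bin j (row-stochastic).  Rows with no observed
    outgoing transition get the uniform distribution so every row sums
    to 1.  The field M[k, l] = W[bin(x_k), bin(x_l)].
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("series too short for a transition field")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    assign, edges = _quantile_bins(x, n_bins)
    q = max(int(assign.max()) + 1, 1)
    counts = np.zeros((q, q), dtype=np.float64)
    np.add.at(counts, (assign[:-1], assign[1:]), 1.0)
    rowsum = counts.sum(axis=1, keepdims=True)
    W = np.where(rowsum > 0, counts / np.where(rowsum == 0, 1, rowsum), 1.0 / q)
    M = W[assign[:, None], assign[None, :]]
    return M, TransitionMatrix(W, edges)


def fuse(
    rp: np.ndarray,
    gaf: np.ndarray,
    mtf_img: np.ndarray,
    axis: str = "channel",
) -> BeatImageStack:
    """Stack the three encodings in fixed (RP, GAF, MTF) order.

    axis "channel" -> shape (3, L, L); axis "height" -> (1, 3L, L), the
    ablation-style concatenation in the height dimension.
    """
    mats = [np.asarray(m, dtype=np.float64) for m in (rp, gaf, mtf_img)]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats) or len(shape) != 2 or shape[0] != shape[1]:
        raise ValueError(
            f"channel shapes must be equal and square, got {[m.shape for m in mats]}"
        )
    if axis == "channel":
        return BeatImageStack(np.stack(mats, axis=0))
    if axis == "height":
        return BeatImageStack(np.concatenate(mats, axis=0)[None, :, :])
    raise ValueError(f"unknown fuse axis {axis!r}")


def export_channel(stack: BeatImageStack, channel: int, path) -> None:
    """Write one channel as an 8-bit lossless PNG for visual inspection.

    Values are min-max scaled per image (a display transform only; the
    numeric arrays in the stack are the canonical data).
    """
    from PIL import Image

    img = np.asarray(stack.channels[channel], dtype=np.float64)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    Image.fromarray((scaled * 255).round().astype(np.uint8), mode="L").save(path)


def encode_beat(values: np.ndarray, config: ImagingConfig | None = None) -> BeatImageStack:
    """Full per-beat encoding: normalize -> RP + GAF + MTF -> fuse."""
    cfg = config or ImagingConfig()
    values = np.asarray(values, dtype=np.float64)
    rp = recurrence(values, cfg.rp_epsilon, cfg.rp_mode)
    xn = normalize(values, cfg.gaf_range)
    if cfg.gaf_kind == "gasf":
        gaf_img = gasf(xn)
    elif cfg.gaf_kind == "gadf":
        gaf_img = gadf(xn, cfg.gadf_variant)
    else:
        raise ValueError(f"unknown gaf_kind {cfg.gaf_kind!r}")
    mtf_img, _ = mtf(values, cfg.mtf_bins)
    return fuse(rp, gaf_img, mtf_img, cfg.fuse_axis)
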