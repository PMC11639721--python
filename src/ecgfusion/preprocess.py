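"""Denoising, beat segmentation, resampling and data partitioning.

The pipeline order follows clinical convention: the whole record is
bandpass-filtered first (0.5-50 Hz by default, removing baseline drift and
powerline interference), then fixed-length windows are cut around the
annotated R peaks (144 samples before, 180 after at 360 Hz -> 324 samples),
and each window is resampled to the image side length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .wfdb_io import AamiClass, EcgRecord, map_symbol

__all__ = ["Beat", "DataSplit", "bandpass", "segment", "resample_beat", "split"]

DEFAULT_PRE = 144
DEFAULT_POST = 180


@dataclass
class Beat:
    """A fixed-length single-lead window labelled with its AAMI class."""

    values: np.ndarray
    label: AamiClass
    source_record: str = ""
    r_peak_index: int = -1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class DataSplit:
    """Disjoint train / validation / test partitions of a beat list."""

    train: list[Beat] = field(default_factory=list)
    validation: list[Beat] = field(default_factory=list)
    test: list[Beat] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def bandpass(
    x: np.ndarray,
    fs: float,
    low_hz: float = 0.5,
    high_hz: float = 50.0,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass.

    The Butterworth filter is applied forward-backward (``filtfilt``), so
    the passband gain is ~1, the effective attenuation is squared, and -
    crucially for beat windowing - the R peak is not shifted relative to
    its annotation.  The default order 6 suppresses 60 Hz powerline
    interference to below 7% amplitude while leaving 10 Hz QRS content
    untouched.

    Raises ``ValueError`` when the sampling rate cannot represent the band.
    """
    x = np.asarray(x, dtype=np.float64)
    if fs <= 2 * high_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {high_hz} Hz band edge"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def segment(
    record: EcgRecord,
    pre_samples: int = DEFAULT_PRE,
    post_samples: int = DEFAULT_POST,
) -> list[Beat]:
    """Cut one window ``[r - pre, r + post)`` per annotated beat.

    Annotations whose symbol is not a beat (rhythm marks, noise, ...) are
    ignored, and windows that would leave the record bounds are dropped.
    """
    if pre_samples <= 0 or post_samples <= 0:
        raise ValueError("pre_samples and post_samples must be positive")
    n = len(record.samples)
    beats: list[Beat] = []
    for r, symbol in record.annotations:
        label = map_symbol(symbol)
        if label is None:
            continue
        lo, hi = r - pre_samples, r + post_samples
        if lo < 0 or hi > n:
            continue
        beats.append(
            Beat(record.samples[lo:hi].copy(), label, record.record_id, r)
        )
    return beats


def resample_beat(values: np.ndarray, target_len: int) -> np.ndarray:
    """Resample a beat window to ``target_len`` samples.

    Linear interpolation on an endpoint-aligned grid: constants are
    preserved exactly and ``target_len == len(values)`` is the identity.
    The beats are already band-limited well below the new Nyquist rate
    (50 Hz content, 324 -> 224 samples over the same 0.9 s window), so no
    extra anti-aliasing stage is needed.
    """
    values = np.asarray(values, dtype=np.float64)
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    n = len(values)
    if n == target_len:
        return values.copy()
    old = np.arange(n, dtype=np.float64)
    new = np.linspace(0.0, n - 1, target_len)
    return np.interp(new, old, values)


def split(
    beats: list[Beat],
    test_fraction: float = 0.2,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> DataSplit:
    """Seeded stratified split into train / validation / test.

    The test set is drawn per class first; the validation set is then a
    fraction of the remaining *training* portion (it never touches test
    beats).  A class too small to appear in every partition stays entirely
    in the training set, with a warning.
    """
    if not 0 < test_fraction < 1 or not 0 <= val_fraction < 1:
        raise ValueError("fractions must lie in (0, 1)")
    if test_fraction + (1 - test_fraction) * val_fraction >= 1:
        raise ValueError("fractions leave no training data")

    rng = np.random.default_rng(seed)
    out = DataSplit()
    labels = np.array([int(b.label) for b in beats])
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        n_val = int(round(val_fraction * (len(idx) - n_test)))
        if n_test == 0 or n_val == 0 or len(idx) - n_test - n_val == 0:
            warnings.warn(
                f"class {AamiClass(cls).name} has too few beats "
                f"({len(idx)}) to stratify; kept in train only",
                stacklevel=2,
            )
            out.train.extend(beats[i] for i in idx)
            continue
        test_idx = idx[:n_test]
        val_idx = idx[n_test : n_test + n_val]
        train_idx = idx[n_test + n_val :]
        out.test.extend(beats[i] for i in test_idx)
        out.validation.extend(beats[i] for i in val_idx)
        out.train.extend(beats[i] for i in train_idx)
    return out
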