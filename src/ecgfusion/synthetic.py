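"""Synthetic five-class ECG beats and annotated records.

Every pipeline stage is testable without downloading anything: beats are
sums of Gaussian bumps (P, Q, R, S, T waves) with class-distinct
morphology following textbook arrhythmia features -

* **N**    normal P-QRS-T morphology;
* **SVEB** absent/reduced P wave, premature (left-shifted) timing;
* **VEB**  wide QRS (>= 2x width), deep S, no P wave;
* **F**    the average of the N and VEB templates (fusion beat);
* **Q**    low-amplitude randomised morphology (paced/unclassifiable).

Records concatenate beats with class-dependent RR intervals and add
baseline wander, powerline interference and white noise; R-peak
annotations use each class's conventional MIT symbol so records
round-trip through :mod:`ecgfusion.wfdb_io`.  This emulates morphology
separability only - real inter-patient variability, rhythm context and
electrode artefacts are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .imaging import ImagingConfig, encode_beat
from .preprocess import resample_beat
from .wfdb_io import AamiClass, EcgRecord, write_record

__all__ = ["BeatTemplate", "NoiseSpec", "synth_beat", "synth_record", "synth_dataset",
           "CLASS_SYMBOLS"]

# conventional annotation symbol per AAMI class
CLASS_SYMBOLS = {
    AamiClass.N: "N",
    AamiClass.SVEB: "A",
    AamiClass.VEB: "V",
    AamiClass.F: "F",
    AamiClass.Q: "/",
}


@dataclass
class BeatTemplate:
    """Gaussian-bump beat morphology.

    Arrays are ordered (P, Q, R, S, T); centers and widths are fractions
    of the beat window, amplitudes are mV.
    """

    amplitudes: tuple = (0.15, -0.10, 1.00, -0.25, 0.30)
    centers: tuple = (0.22, 0.425, 0.444, 0.47, 0.65)
    widths: tuple = (0.025, 0.008, 0.012, 0.010, 0.060)
    qrs_width_mult: float = 1.0
    p_presence: float = 1.0      # probability the P bump is drawn at all
    timing_jitter: float = 0.01  # s.d. of per-beat center shift (fraction)
    amp_jitter: float = 0.10     # s.d. of multiplicative amplitude jitter
    noise_sd: float = 0.02       # beat-level white noise (mV)


_N = BeatTemplate()
_SVEB = replace(_N, amplitudes=(0.05, -0.10, 0.95, -0.25, 0.25),
                centers=(0.18, 0.385, 0.404, 0.43, 0.60), p_presence=0.2)
_VEB = replace(_N, amplitudes=(0.0, -0.15, 0.90, -0.70, 0.45),
               widths=(0.025, 0.008, 0.012, 0.010, 0.080),
               qrs_width_mult=2.5, p_presence=0.0)
_F = BeatTemplate(
    amplitudes=tuple((a + b) / 2 for a, b in zip(_N.amplitudes, _VEB.amplitudes)),
    centers=_N.centers,
    widths=tuple((a + b) / 2 for a, b in zip(_N.widths, _VEB.widths)),
    qrs_width_mult=1.75, p_presence=0.5,
)
_Q = replace(_N, amplitudes=(0.05, -0.04, 0.40, -0.10, 0.12),
             widths=(0.03, 0.015, 0.030, 0.020, 0.070),
             p_presence=0.5, amp_jitter=0.35, timing_jitter=0.03)

DEFAULT_TEMPLATES = {
    AamiClass.N: _N,
    AamiClass.SVEB: _SVEB,
    AamiClass.VEB: _VEB,
    AamiClass.F: _F,
    AamiClass.Q: _Q,
}


@dataclass
class NoiseSpec:
    """Record-level contamination: baseline wander, powerline, white noise."""

    baseline_amp: float = 0.10     # mV
    baseline_hz: float = 0.3
    powerline_amp: float = 0.05    # mV
    powerline_hz: float = 60.0     # the database's mains frequency; 50 for EU
    white_sd: float = 0.03         # mV

    def validate(self):
        if min(self.baseline_amp, self.powerline_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")


def synth_beat(
    aami_class: AamiClass | int,
    fs: float = 360.0,
    length: int = 324,
    template: BeatTemplate | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One seeded beat window (mV) for the given class."""
    if length < 16:
        raise ValueError("length must be >= 16")
    try:
        cls = AamiClass(aami_class)
    except ValueError as exc:
        raise ValueError(f"invalid AAMI class {aami_class!r}") from exc
    tpl = template or DEFAULT_TEMPLATES[cls]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t = np.arange(length) / length
    beat = np.zeros(length)
    for w, (amp, center, width) in enumerate(
        zip(tpl.amplitudes, tpl.centers, tpl.widths)
    ):
        draw_p = rng.random()           # consumed even when skipped, for alignment
        jit_c = rng.normal(0, tpl.timing_jitter)
        jit_a = 1 + rng.normal(0, tpl.amp_jitter)
        if w == 0 and draw_p >= tpl.p_presence:
            continue
        if amp == 0:
            continue
        width_eff = width * (tpl.qrs_width_mult if w in (1, 2, 3) else 1.0)
        beat += amp * jit_a * np.exp(-((t - center - jit_c) ** 2) / (2 * width_eff**2))
    if tpl.noise_sd > 0:
        beat += rng.normal(0, tpl.noise_sd, length)
    return beat


# per-class RR interval preceding the beat, seconds (ectopics are premature)
_RR_SECONDS = {
    AamiClass.N: 0.95,
    AamiClass.SVEB: 0.90,
    AamiClass.VEB: 0.90,
    AamiClass.F: 0.92,
    AamiClass.Q: 0.95,
}


def synth_record(
    n_beats: int,
    classes=None,
    fs: float = 360.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    beat_length: int = 324,
    r_offset: int = 144,
    path: str | Path | None = None,
    record_id: str = "synth",
) -> EcgRecord:
    """A whole annotated record: beats + class-dependent RR + noise.

    ``classes`` is either an explicit class sequence (length ``n_beats``)
    or a length-5 proportion vector (default: uniform).  When ``path`` is
    given the record is also written in WFDB format (two identical leads,
    exercising lead selection).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    noise = noise or NoiseSpec()
    noise.validate()
    rng = np.random.default_rng(seed)

    if classes is None:
        classes = np.full(5, 0.2)
    classes = np.asarray(classes)
    if classes.ndim == 1 and len(classes) == 5 and classes.dtype.kind == "f":
        p = classes / classes.sum()
        seq = rng.choice(5, size=n_beats, p=p)
    else:
        if len(classes) != n_beats:
            raise ValueError("class sequence length must equal n_beats")
        seq = classes.astype(int)

    lead_in = beat_length
    positions, annotations = [], []
    pos = lead_in
    for c in seq:
        rr = int(round(_RR_SECONDS[AamiClass(int(c))] * fs))
        positions.append(pos)
        annotations.append((pos + r_offset, CLASS_SYMBOLS[AamiClass(int(c))]))
        pos += max(rr, beat_length)
    total = pos + beat_length

    sig = np.zeros(total)
    for start, c in zip(positions, seq):
        sig[start : start + beat_length] += synth_beat(
            int(c), fs, beat_length, seed=rng
        )

    t = np.arange(total) / fs
    if noise.baseline_amp:
        sig += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp:
        sig += noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_hz * t)
    if noise.white_sd:
        sig += rng.normal(0, noise.white_sd, total)

    record = EcgRecord(sig, fs, record_id, annotations)
    if path is not None:
        write_record(
            Path(path) / record_id,
            np.stack([sig, sig * 0.6], axis=1),  # second lead: scaled copy
            fs,
            annotations,
            lead_names=["MLII", "V1"],
        )
    return record


def synth_dataset(
    n_per_class: dict,
    image_size: int = 64,
    seed: int = 0,
    imaging: ImagingConfig | None = None,
    beat_length: int = 324,
    fs: float = 360.0,
    return_beats: bool = False,
):
    """Fused image stacks + labels straight through the encoding pipeline.

    Each requested beat runs beat -> resample(image_size) -> RP/GAF/MTF ->
    fuse; the class histogram equals the request exactly and everything is
    deterministic per seed.
    """
    if any(n < 1 for n in n_per_class.values()):
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = imaging or ImagingConfig()

    stacks, labels, beats = [], [], []
    for cls in sorted(n_per_class, key=lambda c: int(AamiClass(c))):
        for _ in range(n_per_class[cls]):
            beat = synth_beat(cls, fs, beat_length, seed=rng)
            series = resample_beat(beat, image_size)
            stacks.append(encode_beat(series, cfg).channels)
            labels.append(int(AamiClass(cls)))
            beats.append(beat)
    X = np.stack(stacks).astype(np.float32)
    y = np.asarray(labels, dtype=np.int64)
    if return_beats:
        return X, y, np.stack(beats)
    return X, y
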