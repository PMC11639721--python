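"""Reading and writing single-lead ECG records in the WFDB file layout.

The MIT-BIH Arrhythmia Database ships as WFDB records: a plain-text header
(``.hea``), a binary signal file (``.dat``, here always format 16 =
little-endian int16), and a binary annotation file (``.atr``) holding beat
marks as (sample index, symbol) pairs.  This module implements the small
subset of the format needed to round-trip such records, plus the mapping
from MIT-BIH annotation symbols to the five AAMI heartbeat super-classes
(N, SVEB, VEB, F, Q).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

__all__ = [
    "AamiClass",
    "EcgRecord",
    "map_symbol",
    "read_record",
    "write_record",
    "BEAT_SYMBOLS",
    "DEFAULT_PACED_RECORDS",
]


class AamiClass(IntEnum):
    """The five AAMI EC57 heartbeat super-classes, coded 0-4."""

    N = 0      # normal and bundle-branch-block beats
    SVEB = 1   # supraventricular ectopic beats
    VEB = 2    # ventricular ectopic beats
    F = 3      # fusion of ventricular and normal
    Q = 4      # paced / unclassifiable


# MIT annotation code <-> symbol (subset of the standard WFDB code table).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    22: '"', 25: "B", 28: "+", 30: "?", 31: "!", 34: "e", 35: "n",
    37: "x", 38: "f", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

# AAMI class membership by annotation symbol:
#   N    normal, left/right bundle branch block, atrial escape, nodal escape
#   SVEB atrial premature, aberrated atrial premature, nodal premature,
#        supraventricular premature
#   VEB  premature ventricular contraction, ventricular escape
#   F    fusion of ventricular and normal
#   Q    paced, fusion of paced and normal, unclassifiable
_SYMBOL_TO_AAMI = {
    "N": AamiClass.N, "L": AamiClass.N, "R": AamiClass.N,
    "e": AamiClass.N, "j": AamiClass.N,
    "A": AamiClass.SVEB, "a": AamiClass.SVEB, "J": AamiClass.SVEB,
    "S": AamiClass.SVEB,
    "V": AamiClass.VEB, "E": AamiClass.VEB,
    "F": AamiClass.F,
    "/": AamiClass.Q, "f": AamiClass.Q, "Q": AamiClass.Q,
}

BEAT_SYMBOLS = frozenset(_SYMBOL_TO_AAMI)

# Records from paced patients conventionally excluded from AAMI evaluation.
# Configurable: pass a different blocklist where needed.
DEFAULT_PACED_RECORDS = ("102", "104", "107", "217")

# Annotation pseudo-codes.
_EOF = 0
_SKIP = 59
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63


def map_symbol(symbol: str) -> AamiClass | None:
    """Map a single-character annotation symbol to its AAMI class.

    Non-beat symbols (rhythm changes, noise marks, comments, ...) and any
    unknown symbol map to ``None``.
    """
    return _SYMBOL_TO_AAMI.get(symbol)


@dataclass
class EcgRecord:
    """A sampled single-lead ECG with annotated beat marks.

    Attributes
    ----------
    samples : np.ndarray
        Signal in physical units (mV), one lead.
    fs : float
        Sampling rate in Hz, > 0.
    record_id : str
        Record name (file stem in the WFDB layout).
    annotations : list[tuple[int, str]]
        ``(sample_index, symbol)`` pairs with strictly increasing indices.
    """

    samples: np.ndarray
    fs: float
    record_id: str
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        idx = [i for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation sample indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation sample index outside the signal")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def _parse_gain_field(token: str) -> tuple[float, float | None]:
    """Parse a header gain token like ``200``, ``200(12)`` or ``200(12)/mV``.

    Returns (gain, baseline or None).
    """
    token = token.split("/")[0]
    baseline = None
    if "(" in token:
        token, rest = token.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(token)
    if gain == 0:
        gain = 200.0  # WFDB convention for unspecified gain
    return gain, baseline


def read_record(
    path: str | Path,
    lead: str = "MLII",
    annotator: str = "atr",
) -> EcgRecord:
    """Read a WFDB record (header + format-16 signal + annotations).

    Parameters
    ----------
    path : path to the record without extension, e.g. ``data/100``.
    lead : preferred signal description; falls back to channel 0 when no
        channel carries that name (header naming varies across dialects).
    annotator : annotation file extension (default ``atr``).

    Returns the requested lead only, converted to physical units.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"header file not found: {hea}")

    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_id = head[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0

    sig_lines = lines[1 : 1 + nsig]
    names, gains, baselines, zeros = [], [], [], []
    dat_name = None
    for ln in sig_lines:
        f = ln.split()
        dat_name = f[0]
        fmt = f[1].split("x")[0].split(":")[0]
        if int(fmt) != 16:
            raise IOError(f"unsupported signal format {f[1]} (only 16 supported)")
        gain, baseline = _parse_gain_field(f[2]) if len(f) > 2 else (200.0, None)
        adc_zero = int(f[4]) if len(f) > 4 else 0
        gains.append(gain)
        baselines.append(adc_zero if baseline is None else baseline)
        zeros.append(adc_zero)
        names.append(f[8] if len(f) > 8 else f"ch{len(names)}")

    dat = path.parent / dat_name
    if not dat.exists():
        raise IOError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if nsamp and raw.size < nsamp * nsig:
        raise IOError(
            f"signal file truncated: expected {nsamp * nsig} samples, got {raw.size}"
        )
    if nsamp:
        raw = raw[: nsamp * nsig]
    sig = raw.reshape(-1, nsig)

    if lead in names:
        ch = names.index(lead)
    else:
        ch = 0
    physical = (sig[:, ch].astype(np.float64) - baselines[ch]) / gains[ch]

    annotations: list[tuple[int, str]] = []
    atr = path.with_suffix(f".{annotator}")
    if atr.exists():
        annotations = _read_annotations(atr)

    return EcgRecord(physical, fs, record_id, annotations)


def _read_annotations(path: Path) -> list[tuple[int, str]]:
    data = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        inc = word & 0x3FF
        if code == _EOF and inc == 0:
            break
        if code == _SKIP and inc == 0:
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += inc + (inc & 1)  # aux string, padded to even length
        else:
            t += inc
            out.append((t, _CODE_TO_SYMBOL.get(code, "?")))
    return out


def write_record(
    path: str | Path,
    signals: np.ndarray,
    fs: float,
    annotations: list[tuple[int, str]] | None = None,
    *,
    lead_names: list[str] | None = None,
    gain: float = 200.0,
    annotator: str = "atr",
) -> Path:
    """Write signals + annotations as a WFDB format-16 record.

    ``signals`` is (nsamples,) or (nsamples, nsig) in mV; values are
    quantised to int16 ADC units with the given gain.  Returns the header
    path.  Used by the synthetic generator so every pipeline stage can be
    exercised on disk without any download.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sig = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    if sig.shape[0] == 1 and sig.ndim == 2 and np.asarray(signals).ndim == 1:
        sig = sig.T
    nsamp, nsig = sig.shape
    if lead_names is None:
        lead_names = ["MLII"] + [f"V{i}" for i in range(1, nsig)]

    adc = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")
    (path.parent / f"{path.name}.dat").write_bytes(adc.reshape(-1).tobytes())

    lines = [f"{path.name} {nsig} {fs:g} {nsamp}"]
    for ch in range(nsig):
        col = adc[:, ch].astype(np.int64)
        checksum = int(np.int16(col.sum() & 0xFFFF))
        lines.append(
            f"{path.name}.dat 16 {gain:g} 11 0 {int(col[0])} {checksum} 0 {lead_names[ch]}"
        )
    (path.parent / f"{path.name}.hea").write_text("\n".join(lines) + "\n")

    if annotations is not None:
        _write_annotations(path.parent / f"{path.name}.{annotator}", annotations)
    return path.parent / f"{path.name}.hea"


def _write_annotations(path: Path, annotations: list[tuple[int, str]]) -> None:
    buf = bytearray()
    t_prev = 0
    for sample, symbol in annotations:
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"no annotation code for symbol {symbol!r}")
        delta = sample - t_prev
        if delta < 0:
            raise ValueError("annotation sample indices must be non-decreasing")
        if delta > 0x3FF:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        t_prev = sample
    buf += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(buf))
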