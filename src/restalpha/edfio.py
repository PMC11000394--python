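"""Minimal EDF (16-bit European Data Format) reader/writer and the Recording type.

Only the plain-EDF feature set needed here is implemented: one-second data
records, a common sampling rate across EEG channels, physical units of µV.
Channel labels like ``"EEG Fp1-Ref"`` are normalized against the montage on
read; channels that do not resolve are kept but flagged.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import FormatError, ParameterError, RangeError, UnsupportedLayoutError
from .montage import Montage, standard_montage

__all__ = ["Recording", "read_edf", "write_edf", "normalize_label",
           "DEFAULT_PHYS_MIN", "DEFAULT_PHYS_MAX"]

# Default physical range: 0.1 µV/bit over the full int16 range.
DEFAULT_PHYS_MIN = -3276.8
DEFAULT_PHYS_MAX = 3276.7
_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class Recording:
    """One subject's continuous multichannel EEG in µV."""

    subject_id: str
    channels: tuple[str, ...]
    fs: float
    data: np.ndarray  # channels x samples, µV
    reference: str = "Cz"
    annotations: list = field(default_factory=list)
    unmapped_channels: tuple[str, ...] = ()

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ParameterError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        up = [c.upper() for c in self.channels]
        if name.upper() not in up:
            raise ParameterError(f"channel {name!r} not in recording")
        return up.index(name.upper())

    def get(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy_with(self, **kw) -> "Recording":
        if "data" in kw:
            kw["data"] = np.asarray(kw["data"], dtype=np.float64)
        out = replace(self, **kw)
        if "data" not in kw:
            out.data = self.data.copy()
        return out


def normalize_label(label: str, montage: Optional[Montage] = None) -> Optional[str]:
    """Map an EDF signal label to a canonical montage name, or None.

    Handles 'EEG Fp1-Ref', 'eeg t7 - ref', bare 'FP1', etc.
    """
    montage = montage if montage is not None else standard_montage()
    s = label.strip()
    if s.upper().startswith("EEG"):
        s = s[3:].strip()
    s = s.split("-")[0].strip()
    if s and s in montage:
        return montage.canonical(s)
    return None


def _ascii_field(value: str, width: int) -> bytes:
    raw = value.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def _fmt_float(x: float, width: int = 8) -> bytes:
    for fmt in (f"{x:g}", f"{x:.4f}", f"{x:.2f}", f"{x:.1f}", f"{x:.0f}"):
        if len(fmt) <= width:
            return _ascii_field(fmt, width)
    raise FormatError(f"cannot format {x} in {width} ascii chars")


def write_edf(recording: Recording, path,
              phys_min: float = DEFAULT_PHYS_MIN,
              phys_max: float = DEFAULT_PHYS_MAX,
              startdate: Optional[_dt.datetime] = None) -> None:
    """Write a Recording as plain 16-bit EDF with one-second data records.

    The recording must span an integer number of seconds and its sampling
    rate must be an integer.  Raises RangeError if any sample falls outside
    the declared physical range — nothing is silently clipped.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = recording.data.shape
    if n_samp % fs != 0:
        raise ParameterError("recording must span an integer number of seconds")
    n_records = n_samp // fs
    if phys_max <= phys_min:
        raise ParameterError("physical max must exceed physical min")
    lo, hi = recording.data.min(initial=0.0), recording.data.max(initial=0.0)
    if lo < phys_min or hi > phys_max:
        raise RangeError(
            f"signal range [{lo:.2f}, {hi:.2f}] µV exceeds declared physical "
            f"range [{phys_min}, {phys_max}] µV")

    # A fixed start date keeps output byte-identical across runs.
    when = startdate if startdate is not None else _dt.datetime(2000, 1, 1, 0, 0, 0)

    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field(recording.subject_id, 80)
    header += _ascii_field(f"reference {recording.reference}", 80)
    header += _ascii_field(when.strftime("%d.%m.%y"), 8)
    header += _ascii_field(when.strftime("%H.%M.%S"), 8)
    header += _ascii_field(str(256 * (1 + n_ch)), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(str(n_records), 8)
    header += _ascii_field("1", 8)
    header += _ascii_field(str(n_ch), 4)

    labels = [f"EEG {c}-Ref" for c in recording.channels]
    per_sig = [
        b"".join(_ascii_field(lab, 16) for lab in labels),
        b"".join(_ascii_field("AgAgCl electrode", 80) for _ in labels),
        b"".join(_ascii_field("uV", 8) for _ in labels),
        b"".join(_fmt_float(phys_min) for _ in labels),
        b"".join(_fmt_float(phys_max) for _ in labels),
        b"".join(_ascii_field(str(_DIG_MIN), 8) for _ in labels),
        b"".join(_ascii_field(str(_DIG_MAX), 8) for _ in labels),
        b"".join(_ascii_field("", 80) for _ in labels),
        b"".join(_ascii_field(str(fs), 8) for _ in labels),
        b"".join(_ascii_field("", 32) for _ in labels),
    ]
    header += b"".join(per_sig)

    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((recording.data - phys_min) / scale).astype(np.int64) + _DIG_MIN
    digital = digital.astype("<i2")

    # record-major layout: per record, all samples of ch0, then ch1, ...
    blocks = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(blocks).tobytes())


def _parse_float(raw: bytes, name: str) -> float:
    try:
        return float(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError):
        raise FormatError(f"malformed EDF header field {name!r}: {raw!r}") from None


def _parse_int(raw: bytes, name: str) -> int:
    try:
        return int(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError):
        raise FormatError(f"malformed EDF header field {name!r}: {raw!r}") from None


def read_edf(path, montage: Optional[Montage] = None) -> Recording:
    """Read a plain EDF file into a Recording in physical units (µV).

    Channel labels are normalized against the montage; labels that do not
    resolve keep their raw (stripped) name and are listed in
    ``unmapped_channels``.
    """
    montage = montage if montage is not None else standard_montage()
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError("file shorter than the fixed 256-byte EDF header")

    subject_id = raw[8:88].decode("ascii", errors="replace").strip()
    header_bytes = _parse_int(raw[184:192], "header bytes")
    n_records = _parse_int(raw[236:244], "number of data records")
    record_dur = _parse_float(raw[244:252], "record duration")
    n_ch = _parse_int(raw[252:256], "number of signals")
    if n_ch <= 0:
        raise FormatError("malformed EDF header field 'number of signals': "
                          f"non-positive value {n_ch}")
    if header_bytes != 256 * (1 + n_ch):
        raise FormatError("malformed EDF header field 'header bytes': "
                          f"{header_bytes} != {256 * (1 + n_ch)}")
    if record_dur <= 0:
        raise FormatError("malformed EDF header field 'record duration': "
                          f"{record_dur}")

    # Per-signal header fields are stored block-wise: all labels, then all
    # transducer strings, etc.  Widths in file order:
    widths = {"label": 16, "transducer": 80, "phys_dim": 8, "phys_min": 8,
              "phys_max": 8, "dig_min": 8, "dig_max": 8, "prefilter": 80,
              "samples_per_record": 8, "reserved": 32}
    offsets, pos = {}, 256
    for key, w in widths.items():
        offsets[key] = pos
        pos += w * n_ch

    def sig_field(key: str, i: int) -> bytes:
        w = widths[key]
        start = offsets[key] + i * w
        return raw[start: start + w]

    labels = [sig_field("label", i).decode("ascii", errors="replace").strip()
              for i in range(n_ch)]
    pmins = [_parse_float(sig_field("phys_min", i), "physical min")
             for i in range(n_ch)]
    pmaxs = [_parse_float(sig_field("phys_max", i), "physical max")
             for i in range(n_ch)]
    dmins = [_parse_int(sig_field("dig_min", i), "digital min")
             for i in range(n_ch)]
    dmaxs = [_parse_int(sig_field("dig_max", i), "digital max")
             for i in range(n_ch)]
    spr = [_parse_int(sig_field("samples_per_record", i), "samples per record")
           for i in range(n_ch)]

    if len(set(spr)) != 1:
        raise UnsupportedLayoutError(
            f"channels have differing samples-per-record: {sorted(set(spr))}")
    samples_per_record = spr[0]
    fs = samples_per_record / record_dur

    expected = header_bytes + 2 * n_records * n_ch * samples_per_record
    if len(raw) < expected:
        raise FormatError(f"file truncated: {len(raw)} bytes < expected {expected}")

    digital = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    digital = digital.reshape(n_records, n_ch, samples_per_record)
    digital = digital.transpose(1, 0, 2).reshape(n_ch, n_records * samples_per_record)

    data = np.empty(digital.shape, dtype=np.float64)
    for i in range(n_ch):
        if dmaxs[i] == dmins[i]:
            raise FormatError("malformed EDF header field 'digital min/max': "
                              "equal values")
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        data[i] = (digital[i].astype(np.float64) - dmins[i]) * scale + pmins[i]

    channels, unmapped = [], []
    for lab in labels:
        canon = normalize_label(lab, montage)
        if canon is None:
            stripped = lab.split("-")[0].removeprefix("EEG").strip() or lab
            channels.append(stripped)
            unmapped.append(stripped)
        else:
            channels.append(canon)

    reference = "unknown"
    rec_field = raw[88:168].decode("ascii", errors="replace").strip()
    if rec_field.startswith("reference "):
        reference = rec_field.split(" ", 1)[1]

    return Recording(subject_id=subject_id, channels=tuple(channels), fs=fs,
                     data=data, reference=reference,
                     unmapped_channels=tuple(unmapped))
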