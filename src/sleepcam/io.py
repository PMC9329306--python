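"""PSG signal, hypnogram and wave-annotation I/O.

Signals travel as EDF (European Data Format): a 256-byte ASCII header, one
256-byte ASCII block per signal, then interleaved little-endian int16 data
records. Each signal carries its own physical/digital calibration, so
channels with different sampling rates (EEG/EMG at 200 Hz, EOG at 100 Hz)
coexist in one file and round-trip at their native rates.

Hypnograms (one stage label per 30-s epoch) and characteristic-wave
annotations (0.5-s grid) are plain UTF-8 CSV with a header row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IoError,
    MissingChannel,
    OffGridInterval,
    UnknownStage,
    UnknownWaveType,
)
from .montage import (
    CANONICAL_NAMES,
    MODALITY_OF,
    ChannelSpec,
    resolve_channel_name,
    validate_montage,
)

STAGES: tuple[str, ...] = ("W", "REM", "N1", "N2", "N3")
NS = "NS"
STAGE_ALPHABET: frozenset[str] = frozenset(STAGES) | {NS}

WAVE_TYPES: frozenset[str] = frozenset({
    "alpha", "arousal", "rem", "sem", "spindle", "kcomplex",
    "delta", "vertex", "sawtooth", "lamf", "blink", "emg_event",
})

EPOCH_LEN_S = 30


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class PsgRecord:
    """A multichannel PSG recording with per-channel metadata.

    ``samples[i]`` is the 1-D float array (µV) for ``channels[i]``; lengths
    differ across channels when sampling rates differ.
    """

    channels: list[ChannelSpec]
    samples: list[np.ndarray]
    start_time: datetime = field(default_factory=lambda: datetime(2000, 1, 1))
    record_id: str = "record"

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.samples):
            raise ValueError("channels and samples length mismatch")
        self.samples = [np.asarray(s, dtype=np.float64) for s in self.samples]

    @property
    def duration_s(self) -> float:
        return len(self.samples[0]) / self.channels[0].sampling_rate

    def index_of(self, name: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise MissingChannel(f"channel {name!r} not in record")

    def get(self, name: str) -> np.ndarray:
        return self.samples[self.index_of(name)]

    def modality_indices(self, modality: str) -> list[int]:
        return [i for i, ch in enumerate(self.channels) if ch.modality == modality]

    def validate(self) -> None:
        """Montage completeness + per-channel sample-count consistency."""
        validate_montage([ch.name for ch in self.channels])
        dur = self.duration_s
        for ch, s in zip(self.channels, self.samples):
            expect = dur * ch.sampling_rate
            if abs(len(s) - expect) > 0.5:
                raise FormatError(
                    f"channel {ch.name}: {len(s)} samples inconsistent with "
                    f"{ch.sampling_rate} Hz x {dur:.1f} s"
                )

    def copy(self) -> "PsgRecord":
        return PsgRecord(
            channels=list(self.channels),
            samples=[s.copy() for s in self.samples],
            start_time=self.start_time,
            record_id=self.record_id,
        )


@dataclass
class Hypnogram:
    """One stage label per 30-s epoch; NS marks epochs unscorable for noise."""

    labels: list[str]
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        bad = [l for l in self.labels if l not in STAGE_ALPHABET]
        if bad:
            raise UnknownStage(f"unknown stage label(s): {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i):
        return self.labels[i]


@dataclass(frozen=True)
class WaveAnnotation:
    """One characteristic-wave interval on the 0.5-s grid.

    The interval is half-open, ``[onset_s, onset_s + duration_s)``, in
    seconds from record start. ``channel`` names a montage channel or
    ``"any"``.
    """

    onset_s: float
    duration_s: float
    wave_type: str
    channel: str = "any"

    def __post_init__(self) -> None:
        if self.wave_type not in WAVE_TYPES:
            raise UnknownWaveType(f"unknown wave type {self.wave_type!r}")
        for value, what in ((self.onset_s, "onset"), (self.duration_s, "duration")):
            if abs(value * 2 - round(value * 2)) > 1e-9:
                raise OffGridInterval(
                    f"{what} {value} s is not a multiple of 0.5 s"
                )
        if self.duration_s <= 0:
            raise OffGridInterval("duration must be a positive multiple of 0.5 s")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class WaveAnnotationSet:
    """Typed characteristic-wave intervals for one record."""

    entries: list[WaveAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def of_type(self, wave_type: str) -> "WaveAnnotationSet":
        return WaveAnnotationSet([e for e in self.entries if e.wave_type == wave_type])

    def overlapping(self, start_s: float, end_s: float) -> "WaveAnnotationSet":
        """Entries whose half-open interval intersects [start_s, end_s)."""
        return WaveAnnotationSet([
            e for e in self.entries if e.onset_s < end_s and e.end_s > start_s
        ])


# ----------------------------------------------------------------------
# EDF
# ----------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:n]
    return b.ljust(n)


def _field(raw: bytes, kind=str):
    text = raw.decode("ascii", errors="replace").strip()
    if kind is str:
        return text
    try:
        return kind(text)
    except ValueError as exc:
        raise FormatError(f"malformed EDF header field {text!r}") from exc


def write_edf(record: PsgRecord, path: str | Path) -> Path:
    """Write a montage-valid record as EDF with 1-s data records.

    Physical calibration is symmetric per channel, sized to the data with a
    5% margin, so the 16-bit quantization step is ``2*pmax/65535`` µV. The
    record is truncated to a whole number of seconds.
    """
    record.validate()
    path = Path(path)
    n_rec = int(math.floor(record.duration_s))
    if n_rec < 1:
        raise IoError("record shorter than one second")
    rates = [int(round(ch.sampling_rate)) for ch in record.channels]
    ns = len(record.channels)

    pmaxs = []
    for s in record.samples:
        m = float(np.max(np.abs(s))) if len(s) else 1.0
        pmaxs.append(max(1, int(math.ceil(m * 1.05))))

    header = b"".join([
        _ascii("0", 8),
        _ascii(record.record_id, 80),
        _ascii("Startdate X X X X", 80),
        _ascii(record.start_time.strftime("%d.%m.%y"), 8),
        _ascii(record.start_time.strftime("%H.%M.%S"), 8),
        _ascii(str(256 * (1 + ns)), 8),
        _ascii("", 44),
        _ascii(str(n_rec), 8),
        _ascii("1", 8),
        _ascii(str(ns), 4),
    ])
    header += b"".join(_ascii(f"{ch.modality} {ch.name}", 16) for ch in record.channels)
    header += b"".join(_ascii("", 80) for _ in range(ns))
    header += b"".join(_ascii("uV", 8) for _ in range(ns))
    header += b"".join(_ascii(str(-p), 8) for p in pmaxs)
    header += b"".join(_ascii(str(p), 8) for p in pmaxs)
    header += b"".join(_ascii(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_ascii(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_ascii("", 80) for _ in range(ns))
    header += b"".join(_ascii(str(r), 8) for r in rates)
    header += b"".join(_ascii("", 32) for _ in range(ns))

    digital = []
    for s, p, r in zip(record.samples, pmaxs, rates):
        scale = 2 * p / (_DIG_MAX - _DIG_MIN)
        d = np.round((s[: n_rec * r] - (-p)) / scale).astype(np.int64) + _DIG_MIN
        digital.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2"))

    try:
        with open(path, "wb") as f:
            f.write(header)
            for rec in range(n_rec):
                for d, r in zip(digital, rates):
                    f.write(d[rec * r: (rec + 1) * r].tobytes())
    except OSError as exc:
        raise IoError(f"cannot write {path}: {exc}") from exc
    return path


def read_edf(
    path: str | Path,
    montage: Sequence[ChannelSpec] | None = None,
    aliases: dict[str, str] | None = None,
) -> PsgRecord:
    """Read an EDF file and return the canonical 9-channel montage.

    Channel labels are matched against the montage after stripping EDF type
    prefixes and applying the optional alias table (recorded-name ->
    canonical-name). All montage channels must be present exactly once.
    Samples are returned in µV at each signal's native rate.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path} is too short to be EDF")
    version = _field(raw[0:8])
    if version != "0":
        raise FormatError(f"{path}: not an EDF file (version field {version!r})")
    record_id = _field(raw[8:88])
    try:
        start = datetime.strptime(
            _field(raw[168:176]) + " " + _field(raw[176:184]), "%d.%m.%y %H.%M.%S"
        )
    except ValueError:
        start = datetime(2000, 1, 1)
    n_rec = _field(raw[236:244], int)
    rec_dur = _field(raw[244:252], float)
    ns = _field(raw[252:256], int)
    if len(raw) < 256 * (1 + ns):
        raise FormatError(f"{path}: truncated EDF header")

    labels = [_field(raw[256 + i * 16: 256 + (i + 1) * 16]) for i in range(ns)]
    # signal-header layout: label16 transducer80 unit8 pmin8 pmax8 dmin8 dmax8
    #                       prefilter80 nsamp8 reserved32
    pos = 256
    pos += 16 * ns + 80 * ns
    units = [_field(raw[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)]
    pos += 8 * ns
    pmin = [_field(raw[pos + i * 8: pos + (i + 1) * 8], float) for i in range(ns)]
    pos += 8 * ns
    pmax = [_field(raw[pos + i * 8: pos + (i + 1) * 8], float) for i in range(ns)]
    pos += 8 * ns
    dmin = [_field(raw[pos + i * 8: pos + (i + 1) * 8], int) for i in range(ns)]
    pos += 8 * ns
    dmax = [_field(raw[pos + i * 8: pos + (i + 1) * 8], int) for i in range(ns)]
    pos += 8 * ns + 80 * ns
    nsamp = [_field(raw[pos + i * 8: pos + (i + 1) * 8], int) for i in range(ns)]

    data_start = 256 * (1 + ns)
    rec_bytes = 2 * sum(nsamp)
    payload = np.frombuffer(raw, dtype="<i2", offset=data_start)
    if n_rec < 0:  # EDF allows -1 for "unknown"; infer from file size
        n_rec = len(payload) * 2 // rec_bytes
    payload = payload[: n_rec * rec_bytes // 2].reshape(n_rec, rec_bytes // 2)

    offsets = np.concatenate([[0], np.cumsum(nsamp)])
    signals: dict[str, tuple[np.ndarray, float]] = {}
    for i, label in enumerate(labels):
        canon = resolve_channel_name(label, aliases)
        if canon is None:
            continue
        if canon in signals:
            raise MissingChannel(f"duplicated montage channel {canon!r} in {path}")
        dig = payload[:, offsets[i]: offsets[i + 1]].reshape(-1).astype(np.float64)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (dig - dmin[i]) * gain + pmin[i]
        unit = units[i].lower()
        if unit in ("mv",):
            phys *= 1e3
        elif unit in ("v",):
            phys *= 1e6
        signals[canon] = (phys, nsamp[i] / rec_dur)

    wanted = [ch.name for ch in montage] if montage else list(CANONICAL_NAMES)
    missing = [n for n in wanted if n not in signals]
    if missing:
        raise MissingChannel(f"montage channel(s) absent from {path}: {missing}")

    channels, samples = [], []
    for name in wanted:
        phys, rate = signals[name]
        channels.append(ChannelSpec(name, MODALITY_OF[name], rate))
        samples.append(phys)
    return PsgRecord(channels=channels, samples=samples,
                     start_time=start, record_id=record_id or path.stem)


# ----------------------------------------------------------------------
# hypnogram CSV
# ----------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"epoch_index": range(len(hyp)), "stage": list(hyp)})
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise IoError(f"cannot write {path}: {exc}") from exc
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path, dtype={"stage": str})
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns epoch_index,stage")
    df = df.sort_values("epoch_index")
    return Hypnogram(labels=[str(s).strip() for s in df["stage"]])


# ----------------------------------------------------------------------
# wave-annotation CSV
# ----------------------------------------------------------------------

def write_wave_labels(waves: WaveAnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(e.onset_s, e.duration_s, e.wave_type, e.channel) for e in waves],
        columns=["onset_s", "duration_s", "wave_type", "channel"],
    )
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise IoError(f"cannot write {path}: {exc}") from exc
    return path


def read_wave_labels(path: str | Path) -> WaveAnnotationSet:
    df = pd.read_csv(path)
    needed = {"onset_s", "duration_s", "wave_type", "channel"}
    if len(df.columns) and not needed <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(needed)}")
    entries = [
        WaveAnnotation(float(r.onset_s), float(r.duration_s),
                       str(r.wave_type), str(r.channel))
        for r in df.itertuples()
    ]
    return WaveAnnotationSet(entries)
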