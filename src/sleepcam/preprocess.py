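"""Noise filtering, resampling, normalization and 30-s epoch segmentation.

The pipeline mirrors clinical practice: zero-phase band-pass filtering per
modality (0.3-35 Hz for EEG/EOG, 10-100 Hz for EMG) plus a powerline notch,
FFT resampling to the canonical 200/100/200 Hz rates, z-score normalization
per channel, and segmentation into 30-s epochs aligned to the hypnogram.
Epochs labelled NS (not scorable) are dropped together with their labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateSignal,
    InvalidBand,
    LabelLengthMismatch,
    ShapeMismatch,
)
from .io import EPOCH_LEN_S, NS, Hypnogram, PsgRecord
from .montage import CANONICAL_RATES, EEG, EMG, EOG

#: samples per 30-s epoch at canonical rates
EPOCH_SAMPLES = {EEG: 6000, EOG: 3000, EMG: 6000}


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass corners plus an optional powerline notch, all in Hz."""

    band_low_hz: float
    band_high_hz: float
    notch_hz: float | None = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise InvalidBand(
                f"need 0 < low < high, got ({self.band_low_hz}, {self.band_high_hz})"
            )


#: Default filter settings per modality (clinical montage, 50 Hz mains).
DEFAULT_FILTERS: dict[str, FilterSpec] = {
    EEG: FilterSpec(0.3, 35.0, 50.0),
    EOG: FilterSpec(0.3, 35.0, 50.0),
    EMG: FilterSpec(10.0, 100.0, 50.0),
}

#: Alternative settings for 60 Hz mains cohorts (wide-band research montage).
MAINS60_FILTERS: dict[str, FilterSpec] = {
    EEG: FilterSpec(0.3, 100.0, 60.0),
    EOG: FilterSpec(0.1, 100.0, 60.0),
    EMG: FilterSpec(10.0, 100.0, 60.0),
}


def _filter_channel(x: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass then IIR notch (Q=30).

    An upper corner at or above 0.99x Nyquist degenerates the band-pass to a
    high-pass (the low-pass half would sit on Nyquist, where a digital
    Butterworth is undefined).
    """
    nyq = rate / 2
    if spec.band_low_hz >= nyq:
        raise InvalidBand(
            f"low corner {spec.band_low_hz} Hz >= Nyquist {nyq} Hz"
        )
    if spec.band_high_hz >= 0.99 * nyq:
        sos = sps.butter(4, spec.band_low_hz, btype="highpass", fs=rate, output="sos")
    else:
        sos = sps.butter(
            4, [spec.band_low_hz, spec.band_high_hz], btype="bandpass",
            fs=rate, output="sos",
        )
    y = sps.sosfiltfilt(sos, x)
    if spec.notch_hz is not None and spec.notch_hz < nyq:
        b, a = sps.iirnotch(spec.notch_hz, Q=30.0, fs=rate)
        y = sps.filtfilt(b, a, y)
    return y


def apply_filters(
    record: PsgRecord, specs: dict[str, FilterSpec] | None = None
) -> PsgRecord:
    """Apply the per-modality band-pass + notch to every channel, zero-phase."""
    specs = specs or DEFAULT_FILTERS
    out = record.copy()
    for i, ch in enumerate(out.channels):
        out.samples[i] = _filter_channel(out.samples[i], ch.sampling_rate, specs[ch.modality])
    return out


def fft_resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Fourier-domain resampling; output length round(n * rate_out / rate_in)."""
    if rate_in <= 0 or rate_out <= 0:
        raise ValueError("rates must be positive")
    x = np.asarray(x, dtype=np.float64)
    n_out = int(round(len(x) * rate_out / rate_in))
    if n_out == len(x):
        return x.copy()
    return sps.resample(x, n_out)


def resample_to_canonical(record: PsgRecord) -> PsgRecord:
    """Bring every channel to the canonical 200/100/200 Hz rates."""
    out = record.copy()
    new_channels = []
    for i, ch in enumerate(out.channels):
        target = CANONICAL_RATES[ch.modality]
        if ch.sampling_rate != target:
            out.samples[i] = fft_resample(out.samples[i], ch.sampling_rate, target)
        new_channels.append(
            type(ch)(ch.name, ch.modality, target, ch.physical_unit)
        )
    out.channels = new_channels
    return out


def normalize_record(record: PsgRecord) -> PsgRecord:
    """Z-score each channel over the whole record (mean 0, sd 1)."""
    out = record.copy()
    for i, ch in enumerate(out.channels):
        x = out.samples[i]
        sd = float(np.std(x))
        if sd < 1e-12:
            raise DegenerateSignal(f"channel {ch.name} has zero variance")
        out.samples[i] = (x - float(np.mean(x))) / sd
    return out


@dataclass
class EpochSet:
    """Modality-grouped 30-s windows aligned to stage labels.

    Arrays are float32 blocks ``eeg (N, 6, 6000)``, ``eog (N, 2, 3000)``,
    ``emg (N, 1, 6000)``; ``labels`` holds the stage per epoch (never NS),
    ``record_ids``/``epoch_indices`` keep per-epoch provenance.
    """

    eeg: np.ndarray
    eog: np.ndarray
    emg: np.ndarray
    labels: np.ndarray
    record_ids: np.ndarray
    epoch_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.epoch_indices is None:
            self.epoch_indices = np.arange(n)
        shapes = {
            "eeg": (n, 6, EPOCH_SAMPLES[EEG]),
            "eog": (n, 2, EPOCH_SAMPLES[EOG]),
            "emg": (n, 1, EPOCH_SAMPLES[EMG]),
        }
        for name, want in shapes.items():
            got = getattr(self, name).shape
            if got != want:
                raise ShapeMismatch(f"{name} block shape {got}, expected {want}")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            eeg=self.eeg[idx], eog=self.eog[idx], emg=self.emg[idx],
            labels=self.labels[idx], record_ids=self.record_ids[idx],
            epoch_indices=self.epoch_indices[idx],
        )

    @staticmethod
    def concatenate(parts: Sequence["EpochSet"]) -> "EpochSet":
        return EpochSet(
            eeg=np.concatenate([p.eeg for p in parts]),
            eog=np.concatenate([p.eog for p in parts]),
            emg=np.concatenate([p.emg for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            record_ids=np.concatenate([p.record_ids for p in parts]),
            epoch_indices=np.concatenate([p.epoch_indices for p in parts]),
        )


def segment_epochs(record: PsgRecord, hyp: Hypnogram) -> EpochSet:
    """Cut a canonical-rate record into labelled 30-s epochs.

    The record yields ``floor(duration/30)`` epochs (a trailing partial epoch
    is dropped); the hypnogram must have exactly that many labels. NS epochs
    are removed together with their labels.
    """
    n_epochs = int(record.duration_s // EPOCH_LEN_S)
    if len(hyp) != n_epochs:
        raise LabelLengthMismatch(
            f"{len(hyp)} labels for {n_epochs} whole epochs"
        )
    blocks = {}
    for mod in (EEG, EOG, EMG):
        idx = record.modality_indices(mod)
        per_epoch = EPOCH_SAMPLES[mod]
        chans = np.stack([record.samples[i][: n_epochs * per_epoch] for i in idx])
        blocks[mod] = (
            chans.reshape(len(idx), n_epochs, per_epoch)
            .transpose(1, 0, 2)
            .astype(np.float32)
        )
    labels = np.array(list(hyp), dtype=object)
    keep = labels != NS
    return EpochSet(
        eeg=blocks[EEG][keep], eog=blocks[EOG][keep], emg=blocks[EMG][keep],
        labels=labels[keep].astype(str),
        record_ids=np.full(int(keep.sum()), record.record_id, dtype=object),
        epoch_indices=np.nonzero(keep)[0],
    )


def prepare_record(
    record: PsgRecord,
    hyp: Hypnogram,
    filters: dict[str, FilterSpec] | None = None,
) -> EpochSet:
    """Full preprocessing pipeline: resample, filter, normalize, segment."""
    rec = resample_to_canonical(record)
    rec = apply_filters(rec, filters)
    rec = normalize_record(rec)
    return segment_epochs(rec, hyp)
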