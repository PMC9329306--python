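"""Synthetic whole-night PSG with ground-truth stage and wave labels.

The generator produces AASM-montage recordings in which each 30-s epoch is
drawn from a 5-state Markov chain, the per-channel background is stage-
conditioned 1/f noise with a stage-typical band emphasis, and discrete
characteristic waves (alpha runs, spindles, K-complexes, slow waves, eye
movements, ...) are injected additively into epochs of their associated
stage, each leaving a typed annotation on the 0.5-s grid. The result is a
fully labelled cohort: signals (EDF), hypnograms (CSV) and wave intervals
(CSV), suitable for training and for auditing CAM explanations against
known wave locations.

The architecture of the synthetic nights is deliberately simple (a sticky
Markov chain, not sleep-cycle dynamics); it exists to encode
stage-discriminative, localizable structure, not clinical realism.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import IncompatibleChannel, InvalidMatrix, OffGridInterval
from .io import (
    NS,
    STAGES,
    Hypnogram,
    PsgRecord,
    WaveAnnotation,
    WaveAnnotationSet,
    write_edf,
    write_hypnogram,
    write_wave_labels,
)
from .montage import CANONICAL_NAMES, CANONICAL_RATES, MODALITY_OF, canonical_montage

_STAGE_IDX = {s: i for i, s in enumerate(STAGES)}

EEG_CHANNELS = ("F3-M2", "F4-M1", "C3-M2", "C4-M1", "O2-M1", "O1-M2")
EOG_CHANNELS = ("E1-M2", "E2-M2")
EMG_CHANNEL = "EMG1-Z"

#: which stages may contain each characteristic wave
STAGE_WAVES: dict[str, tuple[str, ...]] = {
    "alpha": ("W",),
    "arousal": ("W", "N1"),
    "lamf": ("N1", "REM"),
    "vertex": ("N1",),
    "kcomplex": ("N2",),
    "spindle": ("N2",),
    "delta": ("N3",),
    "sawtooth": ("REM",),
    "blink": ("W",),
    "sem": ("W", "N1"),
    "rem": ("W", "REM"),
    "emg_event": ("REM",),
}

#: expected injections per 30-s epoch, by stage
DEFAULT_WAVE_RATES: dict[str, dict[str, float]] = {
    "W": {"alpha": 2.5, "blink": 1.0, "rem": 0.4, "sem": 0.4, "arousal": 0.2},
    "N1": {"vertex": 1.0, "lamf": 1.5, "sem": 0.6, "arousal": 0.2},
    "N2": {"spindle": 2.5, "kcomplex": 1.0},
    "N3": {"delta": 5.0},
    "REM": {"rem": 2.0, "sawtooth": 1.2, "lamf": 1.0, "emg_event": 0.4},
}

#: per-stage EEG background: (emphasis band Hz, band rms fraction, rms µV)
_EEG_BACKGROUND = {
    "W": ((8.0, 13.0), 0.6, 10.0),
    "N1": ((4.0, 7.0), 0.5, 10.0),
    "REM": ((4.0, 7.0), 0.5, 10.0),
    "N2": ((2.0, 14.0), 0.5, 12.0),
    "N3": ((0.5, 2.0), 0.7, 22.0),
}

#: submental muscle tone, rms µV: lowest in REM (atonia), highest awake
_EMG_TONE = {"W": 20.0, "N1": 8.0, "N2": 6.0, "N3": 6.0, "REM": 2.0}

_EOG_RMS = 5.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generation settings.

    ``stage_prior`` defaults to a clinical overnight stage distribution
    (W 19.8%, REM 13.6%, N1 9.7%, N2 42.8%, N3 14.0%); the default
    transition matrix is built so its stationary distribution equals this
    prior while only physiologically adjacent transitions are allowed.
    """

    n_records: int = 40
    record_hours: float = 1.0
    stage_prior: tuple[float, ...] = (0.198, 0.136, 0.097, 0.428, 0.140)
    stage_transition: tuple[tuple[float, ...], ...] | None = None
    wave_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(r) for s, r in DEFAULT_WAVE_RATES.items()}
    )
    noise_amp_uv: float = 1.0      # global multiplier on background amplitudes
    ns_rate: float = 0.05
    ns_artifact_uv: float = 500.0
    delta_band: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    @property
    def prior(self) -> np.ndarray:
        p = np.asarray(self.stage_prior, dtype=np.float64)
        return p / p.sum()

    def transition_matrix(self) -> np.ndarray:
        if self.stage_transition is not None:
            t = np.asarray(self.stage_transition, dtype=np.float64)
        else:
            t = build_transition_matrix(self.prior)
        if t.shape != (5, 5) or (t < 0).any() or np.abs(t.sum(axis=1) - 1).max() > 1e-8:
            raise InvalidMatrix("stage_transition must be 5x5 row-stochastic")
        return t

    @property
    def n_epochs(self) -> int:
        return int(round(self.record_hours * 120))


#: allowed stage moves: the W-N1-N2-N3 depth ladder with REM cycling, plus
#: direct W<->N2 (awakenings out of N2 and rapid sleep re-entry)
_ADJACENCY: dict[str, tuple[str, ...]] = {
    "W": ("N1", "REM", "N2"),
    "N1": ("W", "N2", "REM"),
    "N2": ("N1", "N3", "REM", "W"),
    "N3": ("N2",),
    "REM": ("W", "N1", "N2"),
}


def build_transition_matrix(prior: np.ndarray, stickiness: float = 0.9) -> np.ndarray:
    """Sticky Metropolis-Hastings chain with the given stationary law.

    Proposals are uniform over the adjacency graph; the acceptance step makes
    the move kernel reversible with respect to ``prior``, and blending with
    the identity (``stickiness`` of staying put) preserves stationarity while
    giving stage bouts a mean length of ~10 epochs. A fixture device, not a
    model of sleep-cycle dynamics.
    """
    prior = np.asarray(prior, dtype=np.float64)
    q = np.zeros((5, 5))
    for i, s in enumerate(STAGES):
        nbrs = _ADJACENCY[s]
        for t in nbrs:
            j = _STAGE_IDX[t]
            accept = min(1.0, prior[j] * len(nbrs) / (prior[i] * len(_ADJACENCY[t])))
            q[i, j] = accept / len(nbrs)
        q[i, i] = 1.0 - q[i].sum()
    return stickiness * np.eye(5) + (1.0 - stickiness) * q


def sample_hypnogram(
    config: SyntheticConfig,
    n_epochs: int | None = None,
    rng: np.random.Generator | None = None,
) -> Hypnogram:
    """Markov stage sequence at 30-s resolution, starting awake (W)."""
    t = config.transition_matrix()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n_epochs if n_epochs is not None else config.n_epochs
    labels = []
    state = _STAGE_IDX["W"]
    for _ in range(n):
        labels.append(STAGES[state])
        state = int(rng.choice(5, p=t[state]))
    return Hypnogram(labels=labels)


# ----------------------------------------------------------------------
# backgrounds
# ----------------------------------------------------------------------

def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = float(np.sqrt(np.mean(x * x)))
    return x / r if r > 0 else x


def _pink_noise(n: int, rate: float, rng: np.random.Generator,
                knee_hz: float = 2.0) -> np.ndarray:
    """1/f-amplitude Gaussian noise with a low-frequency knee, unit rms.

    Below ``knee_hz`` the spectrum rolls off instead of diverging,
    mimicking the amplifier high-pass of clinical EEG; without the knee the
    infra-slow drift would dominate every stage's power spectrum and mask
    the stage-typical band emphasis.
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    f[0] = f[1] if n > 1 else 1.0
    amp = 1.0 / np.sqrt(np.maximum(f, knee_hz))
    amp *= np.minimum(1.0, f / knee_hz) ** 1.5
    spec *= amp
    spec[0] = 0.0
    return _unit_rms(np.fft.irfft(spec, n))


def _band_noise(n: int, rate: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise confined to [lo, hi] Hz, unit rms."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(f < lo) | (f > hi)] = 0.0
    return _unit_rms(np.fft.irfft(spec, n))


def synth_background(
    stage: str,
    duration_s: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Stage-conditioned noise floor for every montage channel, in µV.

    EEG channels carry 1/f noise plus a stage-typical band emphasis (alpha
    band awake, theta in N1/REM, broad mixed in N2, high-amplitude slow
    activity in N3). The EMG tone is white high-frequency noise whose
    amplitude is minimal in REM (atonia). EOG is near-flat low-frequency
    noise; discrete eye movements are injected separately as waves.
    """
    if stage not in _STAGE_IDX:
        raise KeyError(f"unknown stage {stage!r}")
    out: dict[str, np.ndarray] = {}
    (lo, hi), band_frac, amp = _EEG_BACKGROUND[stage]
    amp *= config.noise_amp_uv
    for name in EEG_CHANNELS:
        n = int(round(duration_s * CANONICAL_RATES["EEG"]))
        x = (math.sqrt(1 - band_frac**2) * _pink_noise(n, 200.0, rng)
             + band_frac * _band_noise(n, 200.0, lo, hi, rng))
        out[name] = amp * x
    for name in EOG_CHANNELS:
        n = int(round(duration_s * CANONICAL_RATES["EOG"]))
        x = _band_noise(n, 100.0, 0.2, 8.0, rng)
        out[name] = _EOG_RMS * config.noise_amp_uv * x
    n = int(round(duration_s * CANONICAL_RATES["EMG"]))
    x = _band_noise(n, 200.0, 20.0, 99.0, rng)
    out[EMG_CHANNEL] = _EMG_TONE[stage] * config.noise_amp_uv * x
    return out


# ----------------------------------------------------------------------
# characteristic waves
# ----------------------------------------------------------------------

def _hann(n: int) -> np.ndarray:
    return np.hanning(n) if n >= 2 else np.ones(n)


@dataclass(frozen=True)
class _WaveDef:
    modality: str                       # modality the wave lives on
    targets: tuple[tuple[str, float], ...]  # (channel, relative gain)
    dur_range: tuple[float, float]


def _targets(channels: Sequence[str], gains: Sequence[float]):
    return tuple(zip(channels, gains))


_WAVE_DEFS: dict[str, _WaveDef] = {
    "alpha": _WaveDef("EEG", _targets(("O1-M2", "O2-M1", "C3-M2", "C4-M1"),
                                      (1.0, 1.0, 0.4, 0.4)), (1.5, 3.0)),
    "spindle": _WaveDef("EEG", _targets(("C3-M2", "C4-M1", "F3-M2", "F4-M1"),
                                        (1.0, 1.0, 0.5, 0.5)), (0.6, 1.4)),
    "kcomplex": _WaveDef("EEG", _targets(("F3-M2", "F4-M1", "C3-M2", "C4-M1"),
                                         (1.0, 1.0, 0.7, 0.7)), (0.8, 1.3)),
    "delta": _WaveDef("EEG", _targets(("F3-M2", "F4-M1", "C3-M2", "C4-M1", "O1-M2", "O2-M1"),
                                      (1.0, 1.0, 0.8, 0.8, 0.4, 0.4)), (0.0, 0.0)),
    "vertex": _WaveDef("EEG", _targets(("C3-M2", "C4-M1"), (1.0, 1.0)), (0.3, 0.4)),
    "sawtooth": _WaveDef("EEG", _targets(("C3-M2", "C4-M1", "F3-M2", "F4-M1"),
                                         (0.8, 0.8, 0.8, 0.8)), (1.0, 2.5)),
    "lamf": _WaveDef("EEG", _targets(EEG_CHANNELS, (0.7,) * 6), (2.0, 4.0)),
    "arousal": _WaveDef("EEG", _targets(EEG_CHANNELS, (1.0,) * 6), (3.0, 5.0)),
    "blink": _WaveDef("EOG", _targets(EOG_CHANNELS, (1.0, 1.0)), (1.0, 3.0)),
    "sem": _WaveDef("EOG", _targets(EOG_CHANNELS, (1.0, -1.0)), (3.0, 6.0)),
    "rem": _WaveDef("EOG", _targets(EOG_CHANNELS, (1.0, -1.0)), (0.5, 2.0)),
    "emg_event": _WaveDef("EMG", _targets((EMG_CHANNEL,), (1.0,)), (0.5, 2.0)),
}


def sample_wave_duration(wave_type: str, config: SyntheticConfig,
                         rng: np.random.Generator) -> float:
    """Draw a duration (s) for a wave; delta waves last one slow cycle."""
    if wave_type == "delta":
        f = rng.uniform(*config.delta_band)
        return 1.0 / f
    lo, hi = _WAVE_DEFS[wave_type].dur_range
    return float(rng.uniform(lo, hi))


def _waveform(wave_type: str, duration_s: float, rate: float,
              config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """The additive µV waveform for the wave's primary channel."""
    n = max(2, int(round(duration_s * rate)))
    t = np.arange(n) / rate
    if wave_type == "alpha":
        f = rng.uniform(8.0, 13.0)
        return 20.0 * _hann(n) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if wave_type == "spindle":
        f = rng.uniform(11.0, 16.0)
        # Hann envelope: the maximum amplitude sits at the wave's center
        return 30.0 * _hann(n) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if wave_type == "kcomplex":
        # sharp negative deflection immediately followed by a positive wave
        n1 = max(2, int(round(n * 0.35)))
        n2 = n - n1
        neg = -85.0 * np.sin(np.pi * np.arange(n1) / n1)
        pos = 55.0 * np.sin(np.pi * np.arange(n2) / n2)
        return np.concatenate([neg, pos])
    if wave_type == "delta":
        amp = rng.uniform(85.0, 140.0)  # peak above the 75 µV slow-wave criterion
        return -amp * np.sin(2 * np.pi * np.arange(n) / n)
    if wave_type == "vertex":
        return -60.0 * np.sin(np.pi * np.arange(n) / n) ** 3
    if wave_type == "sawtooth":
        f = rng.uniform(2.0, 6.0)
        return 25.0 * _hann(n) * sps.sawtooth(2 * np.pi * f * t, width=0.9)
    if wave_type == "lamf":
        f = rng.uniform(4.0, 7.0)
        return 15.0 * _hann(n) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if wave_type == "arousal":
        # abrupt frequency shift: fast activity riding on the background
        f = rng.uniform(16.0, 30.0)
        return 15.0 * _hann(n) * np.sin(2 * np.pi * f * t)
    if wave_type == "blink":
        f = rng.uniform(0.5, 2.0)
        return 80.0 * _hann(n) * np.abs(np.sin(np.pi * f * t))
    if wave_type == "sem":
        f = rng.uniform(0.25, 0.5)
        return 60.0 * _hann(n) * np.sin(2 * np.pi * f * t)
    if wave_type == "rem":
        # a few steep, randomly timed and signed deflections
        x = np.zeros(n)
        for _ in range(rng.integers(2, 5)):
            center = rng.uniform(0.1, 0.9) * duration_s
            sign = rng.choice([-1.0, 1.0])
            x += sign * np.tanh((t - center) / 0.03)
        x -= x.mean()
        m = np.max(np.abs(x))
        return 80.0 * _hann(n) * (x / m if m > 0 else x)
    if wave_type == "emg_event":
        return 40.0 * _hann(n) * rng.standard_normal(n)
    raise KeyError(f"unknown wave type {wave_type!r}")


def inject_wave(
    signals: dict[str, np.ndarray],
    wave_type: str,
    onset_s: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    duration_s: float | None = None,
    channel: str | None = None,
) -> WaveAnnotation:
    """Add one characteristic wave to the signals, in place.

    ``signals`` maps montage channel names to full-record µV arrays at
    canonical rates. The onset must sit on the 0.5-s grid; the returned
    annotation covers the waveform extent rounded outward to the grid.
    Restricting to an explicit ``channel`` of the wrong modality raises
    IncompatibleChannel.
    """
    if wave_type not in _WAVE_DEFS:
        raise KeyError(f"unknown wave type {wave_type!r}")
    if abs(onset_s * 2 - round(onset_s * 2)) > 1e-9:
        raise OffGridInterval(f"onset {onset_s} s is not on the 0.5-s grid")
    wdef = _WAVE_DEFS[wave_type]
    if channel is not None and MODALITY_OF.get(channel) != wdef.modality:
        raise IncompatibleChannel(
            f"{wave_type} is an {wdef.modality} wave; cannot target {channel!r}"
        )
    if duration_s is None:
        duration_s = sample_wave_duration(wave_type, config, rng)
    rate = CANONICAL_RATES[wdef.modality]
    base = _waveform(wave_type, duration_s, rate, config, rng)
    start = int(round(onset_s * rate))
    targets = wdef.targets if channel is None else tuple(
        (c, g) for c, g in wdef.targets if c == channel
    )
    for name, gain in targets:
        sig = signals[name]
        seg = base[: max(0, len(sig) - start)]
        sig[start: start + len(seg)] += gain * seg
    if wave_type == "arousal":  # body-movement EMG activity accompanies arousals
        emg = signals[EMG_CHANNEL]
        e0 = int(round(onset_s * CANONICAL_RATES["EMG"]))
        ne = max(2, int(round(duration_s * 0.5 * CANONICAL_RATES["EMG"])))
        burst = 30.0 * _hann(ne) * rng.standard_normal(ne)
        seg = burst[: max(0, len(emg) - e0)]
        emg[e0: e0 + len(seg)] += seg
    ann_dur = max(0.5, math.ceil(duration_s / 0.5 - 1e-9) * 0.5)
    primary = wdef.targets[0][0] if channel is None else channel
    return WaveAnnotation(onset_s=float(onset_s), duration_s=float(ann_dur),
                          wave_type=wave_type, channel=primary)


# ----------------------------------------------------------------------
# whole records and cohorts
# ----------------------------------------------------------------------

@dataclass
class SyntheticRecord:
    """One generated night: signals, ground-truth hypnogram, wave labels."""

    record: PsgRecord
    hypnogram: Hypnogram
    waves: WaveAnnotationSet


def _ns_artifact(signals: dict[str, np.ndarray], epoch: int,
                 config: SyntheticConfig, rng: np.random.Generator) -> None:
    """Large movement-like artifact rendering the epoch unscorable."""
    for name in (*EEG_CHANNELS, *EOG_CHANNELS, EMG_CHANNEL):
        rate = CANONICAL_RATES[MODALITY_OF[name]]
        lo = int(epoch * 30 * rate)
        n = int(30 * rate)
        t = np.arange(n) / rate
        drift = config.ns_artifact_uv * np.sin(2 * np.pi * rng.uniform(0.2, 0.7) * t)
        spikes = config.ns_artifact_uv * 0.6 * rng.standard_normal(n) \
            * (rng.random(n) < 0.02)
        signals[name][lo: lo + n] += drift + spikes


def make_record(
    config: SyntheticConfig,
    record_id: str,
    rng: np.random.Generator,
) -> SyntheticRecord:
    """Generate one labelled record at canonical rates."""
    n_epochs = config.n_epochs
    hyp = sample_hypnogram(config, n_epochs, rng)
    stages = list(hyp)

    signals = {name: [] for name in CANONICAL_NAMES}
    for stage in stages:
        bg = synth_background(stage, 30.0, config, rng)
        for name in CANONICAL_NAMES:
            signals[name].append(bg[name])
    signals = {name: np.concatenate(parts) for name, parts in signals.items()}

    ns_mask = rng.random(n_epochs) < config.ns_rate
    entries = []
    labels = []
    for ep, stage in enumerate(stages):
        if ns_mask[ep]:
            _ns_artifact(signals, ep, config, rng)
            labels.append(NS)
            continue
        labels.append(stage)
        for wave_type, rate in config.wave_rates.get(stage, {}).items():
            for _ in range(rng.poisson(rate)):
                dur = sample_wave_duration(wave_type, config, rng)
                slots = 60 - int(math.ceil(dur / 0.5 - 1e-9))
                if slots < 1:
                    continue
                onset = ep * 30.0 + 0.5 * int(rng.integers(0, slots + 1))
                entries.append(inject_wave(signals, wave_type, onset,
                                           config, rng, duration_s=dur))

    record = PsgRecord(
        channels=canonical_montage(),
        samples=[signals[name] for name in CANONICAL_NAMES],
        record_id=record_id,
    )
    return SyntheticRecord(record=record, hypnogram=Hypnogram(labels=labels),
                           waves=WaveAnnotationSet(entries))


def generate_cohort(
    config: SyntheticConfig,
    out_dir: str | Path | None = None,
) -> list[SyntheticRecord]:
    """Generate ``config.n_records`` labelled records.

    With ``out_dir`` set, each record is written as ``<id>.edf`` +
    ``<id>_hypnogram.csv`` + ``<id>_waves.csv``, plus a ``manifest.json``
    holding the seed and a hash of the configuration.
    """
    ss = np.random.SeedSequence(config.seed)
    records = []
    for i, child in enumerate(ss.spawn(config.n_records)):
        rng = np.random.default_rng(child)
        records.append(make_record(config, f"synth-{config.seed:04d}-{i:03d}", rng))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sr in records:
            rid = sr.record.record_id
            write_edf(sr.record, out / f"{rid}.edf")
            write_hypnogram(sr.hypnogram, out / f"{rid}_hypnogram.csv")
            write_wave_labels(sr.waves, out / f"{rid}_waves.csv")
        cfg_repr = json.dumps(
            {k: v for k, v in config.__dict__.items()}, sort_keys=True, default=str
        )
        manifest = {
            "seed": config.seed,
            "n_records": config.n_records,
            "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
            "records": [sr.record.record_id for sr in records],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records
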