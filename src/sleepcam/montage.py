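"""The AASM 9-channel polysomnography montage and channel metadata.

Sleep staging per the AASM manual uses six referential EEG derivations
(frontal, central, occipital, both hemispheres), two EOG derivations and
one submental EMG channel. The canonical sampling rates throughout this
package are 200 Hz (EEG), 100 Hz (EOG) and 200 Hz (EMG).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MissingChannel

EEG, EOG, EMG = "EEG", "EOG", "EMG"

#: canonical channel order: 6 EEG, 2 EOG, 1 EMG
CANONICAL_NAMES: tuple[str, ...] = (
    "F3-M2", "F4-M1", "C3-M2", "C4-M1", "O2-M1", "O1-M2",
    "E1-M2", "E2-M2",
    "EMG1-Z",
)

MODALITY_OF: dict[str, str] = {
    "F3-M2": EEG, "F4-M1": EEG, "C3-M2": EEG, "C4-M1": EEG,
    "O2-M1": EEG, "O1-M2": EEG,
    "E1-M2": EOG, "E2-M2": EOG,
    "EMG1-Z": EMG,
}

#: canonical sampling rate per modality, Hz
CANONICAL_RATES: dict[str, float] = {EEG: 200.0, EOG: 100.0, EMG: 200.0}

#: number of channels per modality in the canonical montage
MODALITY_COUNTS: dict[str, int] = {EEG: 6, EOG: 2, EMG: 1}


@dataclass(frozen=True)
class ChannelSpec:
    """One montage channel: label, modality, rate and physical unit."""

    name: str
    modality: str
    sampling_rate: float
    physical_unit: str = "uV"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.modality not in (EEG, EOG, EMG):
            raise ValueError(f"unknown modality {self.modality!r}")


def canonical_montage() -> list[ChannelSpec]:
    """The default montage at canonical rates, in canonical order."""
    return [
        ChannelSpec(n, MODALITY_OF[n], CANONICAL_RATES[MODALITY_OF[n]])
        for n in CANONICAL_NAMES
    ]


def resolve_channel_name(label: str, aliases: dict[str, str] | None = None) -> str | None:
    """Map a recorded channel label to a canonical montage name.

    Strips optional ``"EEG "``/``"EOG "``/``"EMG "`` type prefixes (common in
    EDF labels), then looks the remainder up in the canonical set and in the
    user-supplied alias table (recorded-name -> canonical-name). Returns None
    when the label does not belong to the montage.
    """
    name = label.strip()
    for prefix in ("EEG ", "EOG ", "EMG "):
        if name.startswith(prefix):
            name = name[len(prefix):].strip()
            break
    if name in MODALITY_OF:
        return name
    if aliases and name in aliases:
        target = aliases[name]
        if target not in MODALITY_OF:
            raise ValueError(f"alias target {target!r} is not a montage channel")
        return target
    return None


def validate_montage(names: list[str]) -> None:
    """Require exactly the 9 canonical channels, each exactly once."""
    seen = set()
    for n in names:
        if n not in MODALITY_OF:
            raise MissingChannel(f"{n!r} is not an AASM montage channel")
        if n in seen:
            raise MissingChannel(f"duplicated montage channel {n!r}")
        seen.add(n)
    missing = set(CANONICAL_NAMES) - seen
    if missing:
        raise MissingChannel(f"missing montage channel(s): {sorted(missing)}")
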