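"""Exception hierarchy for the sleepcam pipeline.

Every contract violation raises a named subclass of :class:`SleepCamError`
so callers (and the CLI) can distinguish user errors from bugs.
"""


class SleepCamError(Exception):
    """Base class for all sleepcam exceptions."""


# --- I/O ---------------------------------------------------------------
class FormatError(SleepCamError):
    """File is not valid EDF/EDF+ (or another expected carrier format)."""


class MissingChannel(SleepCamError):
    """A montage channel is absent from (or duplicated in) the recording."""


class UnknownStage(SleepCamError):
    """A hypnogram label is outside the {W, REM, N1, N2, N3, NS} alphabet."""


class UnknownWaveType(SleepCamError):
    """A wave annotation names a type outside the characteristic-wave set."""


class OffGridInterval(SleepCamError):
    """A wave interval's onset or duration is not a multiple of 0.5 s."""


class IoError(SleepCamError):
    """The output path cannot be written."""


# --- preprocessing -----------------------------------------------------
class InvalidBand(SleepCamError):
    """Filter corners are inconsistent with the channel's sampling rate."""


class DegenerateSignal(SleepCamError):
    """A channel has zero variance and cannot be normalized."""


class LabelLengthMismatch(SleepCamError):
    """Hypnogram length differs from the number of whole 30-s epochs."""


# --- model -------------------------------------------------------------
class ShapeMismatch(SleepCamError):
    """Tensor shapes are inconsistent with the model configuration."""


class ResolutionError(SleepCamError):
    """CAM step length does not divide the 0.5-s annotation grid."""


# --- training ----------------------------------------------------------
class EmptySplit(SleepCamError):
    """A requested train/validation split leaves one side empty."""


class SingleClassData(SleepCamError):
    """Training data contain fewer than two distinct stages."""


class TooFewRecords(SleepCamError):
    """Not enough records for the requested fold count or subset size."""


# --- evaluation --------------------------------------------------------
class LengthMismatch(SleepCamError):
    """Reference and predicted hypnograms have different lengths."""


class EmptyMatrix(SleepCamError):
    """A confusion matrix with zero total epochs cannot yield metrics."""


# --- explainability ----------------------------------------------------
class NoTruePositives(SleepCamError):
    """No epoch has predicted == reference == the requested stage."""


class ZeroPrevalence(SleepCamError):
    """The wave type never occurs among the scored points; enrichment undefined."""


# --- simulation --------------------------------------------------------
class InvalidMatrix(SleepCamError):
    """Stage-transition matrix is not row-stochastic."""


class IncompatibleChannel(SleepCamError):
    """Wave type cannot be injected into the requested channel modality."""
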