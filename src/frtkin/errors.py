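"""Exception hierarchy for the FRT analysis pipeline.

Every error raised deliberately by frtkin derives from :class:`FrtError`,
so callers (and the CLI) can catch one type and report a one-line
diagnostic.
"""


class FrtError(Exception):
    """Base class for all frtkin errors."""


# --- sensor_io ---------------------------------------------------------------

class MalformedLog(FrtError):
    """A sensor log file could not be parsed into a trace."""


class EmptyLog(FrtError):
    """A sensor log contains no samples."""


# --- preprocess --------------------------------------------------------------

class InsufficientSamples(FrtError):
    """Too few samples for the requested operation (resampling needs >= 2)."""


class InvalidCutoff(FrtError):
    """Low-pass cutoff outside (0, rate/2)."""


class NoUsableChannels(FrtError):
    """Neither attitude nor accelerometer channels available for pitch."""


class QuietWindowTooShort(FrtError):
    """The initial quiet window holds fewer than two samples."""


# --- segmentation ------------------------------------------------------------

class NoMovementDetected(FrtError):
    """No excursion of the pitch series exceeds the minimum peak amplitude."""


class NoReturnDetected(FrtError):
    """The series never settles back below the onset threshold after the peak."""


# --- kinematics --------------------------------------------------------------

class InconsistentEvents(FrtError):
    """Phase events do not lie on the pitch series' sample grid."""


class MissingChannels(FrtError):
    """The trace lacks the channels needed for an axis summary."""


class MismatchedTrials(FrtError):
    """Trunk and lumbar results do not belong to the same subject/trial."""


# --- reliability -------------------------------------------------------------

class InsufficientData(FrtError):
    """Sample too small for the requested statistical test."""


class LengthMismatch(FrtError):
    """Paired samples of unequal length."""


class DegenerateMatrix(FrtError):
    """A ratings matrix with zero total variance; ICC undefined."""


class MissingVariable(FrtError):
    """A reliability dataset lacks a required ratings matrix."""


# --- synthetic data ----------------------------------------------------------

class InvalidConfig(FrtError):
    """A simulation or run configuration violates its invariants."""
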