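"""Exception hierarchy shared by all gaitinit modules."""


class GaitInitError(Exception):
    """Base class for all package errors."""


class FormatError(GaitInitError):
    """A trial file or table does not conform to the expected layout."""


class SignalLengthError(GaitInitError):
    """A signal is too short for the requested operation."""


class WindowError(GaitInitError):
    """A requested analysis window does not fit inside the trial."""


class DetectionError(GaitInitError):
    """An event-detection stage failed to find its landmark.

    Carries the name of the failing stage so that pipeline failures are
    atomic and diagnosable.
    """

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class FeasibilityError(GaitInitError):
    """A synthetic trial specification is incompatible with the configured
    detection windows."""


class UsageError(GaitInitError):
    """An operation was called with inconsistent or empty inputs."""
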