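"""Exception and warning types shared across the package."""


class FvtpError(Exception):
    """Base class for all package-specific errors."""


class DegenerateFitError(FvtpError):
    """The two observations cannot constrain a line (equal velocities)."""


class InvalidProfileError(FvtpError):
    """A fitted line violates the force-velocity profile conditions."""


class ConfigurationError(FvtpError):
    """A configuration value is out of its admissible range."""


class NoMovementError(FvtpError):
    """No movement onset could be located in a force trace."""


class NoTakeoffError(FvtpError):
    """No flight phase could be located in a force trace."""


class UndefinedForceError(FvtpError):
    """Force cannot be derived from power at non-positive velocity."""


class InfeasibleVelocityError(FvtpError):
    """Requested velocity lies at or beyond the profile's velocity intercept."""


class UndefinedCorrelationError(FvtpError):
    """Correlation is undefined (zero variance or degenerate input)."""


class AlignmentError(FvtpError):
    """Subject sets do not align across tests."""

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = dict(missing or {})


class ExtrapolationWarning(UserWarning):
    """Fitted intercepts lie far beyond the physiological range."""
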