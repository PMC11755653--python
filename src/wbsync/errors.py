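"""Exception hierarchy for the wbsync pipeline."""


class WbsyncError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WbsyncError):
    """A file could not be parsed as the expected format."""


class MontageError(WbsyncError):
    """Required EEG channels are missing or cannot be matched."""

    def __init__(self, missing, message=None):
        self.missing = tuple(missing)
        super().__init__(message or f"missing channels: {', '.join(self.missing)}")


class SamplingError(WbsyncError):
    """Sampling-rate inconsistency between channels or against the config."""


class ValidationError(WbsyncError):
    """Input data violates a documented invariant."""


class ConfigurationError(WbsyncError):
    """Analysis configuration is inconsistent or incompatible with the data."""


class AlignmentError(WbsyncError):
    """Two time-frequency objects do not share a common grid."""


class DomainError(WbsyncError, ValueError):
    """A numeric argument lies outside its mathematical domain."""
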