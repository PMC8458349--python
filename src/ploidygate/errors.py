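"""Exception hierarchy.

All package errors derive from :class:`PloidygateError` so callers can
distinguish validation problems (bad inputs, bad configuration) from data
problems (too few events, degenerate distributions).
"""


class PloidygateError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PloidygateError):
    """A file or table does not have the expected structure."""


class ValidationError(PloidygateError):
    """Input values violate a documented invariant."""


class ConfigError(ValidationError):
    """A configuration object is internally inconsistent."""


class PairingError(ValidationError):
    """Two collections that must share identifiers do not."""


class FeatureMissingError(PloidygateError):
    """A required per-event feature is absent."""


class InsufficientDataError(PloidygateError):
    """Too few events to support a robust estimate."""


class DegenerateGatingError(PloidygateError):
    """Gate regions collapsed or overlapped; no meaningful delineation."""


class EmptyGateError(PloidygateError):
    """No events in the gated denominator."""


class DegenerateScaleError(PloidygateError):
    """Standardization requested on data with zero spread."""


class PipelineStageError(PloidygateError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
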