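"""Exception hierarchy for tandemrrm."""


class TandemRRMError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TandemRRMError):
    """A text input file violated its format contract."""


class ValidationError(TandemRRMError):
    """A domain object violated one of its invariants."""


class GeometryError(TandemRRMError):
    """Structure geometry insufficient for the requested operation
    (missing atoms, collinear bond vectors, rank-deficient design)."""


class FitError(TandemRRMError):
    """A nonlinear fit failed to converge.

    Carries the last parameter iterate when available."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class UnidentifiableError(FitError):
    """The data carry no information about the requested parameter
    (flat titration, featureless isotherm, constant decay)."""


class PipelineError(TandemRRMError):
    """A pipeline stage failed; message names the stage and the cause."""
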