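"""Exception hierarchy for pulsedecomp."""


class PulseDecompError(Exception):
    """Base class for all pulsedecomp errors."""


class InvalidParameterError(PulseDecompError, ValueError):
    """A parameter violates its documented constraint."""


class UnsupportedKindError(PulseDecompError, TypeError):
    """An operation was applied to a stream of the wrong signal kind."""


class InsufficientDataError(PulseDecompError, ValueError):
    """Too few samples/beats/pairs to carry out the computation."""


class DegenerateFitError(PulseDecompError, ValueError):
    """A regression input has zero variance (no information in the fit)."""


class AlignmentFailureError(PulseDecompError, RuntimeError):
    """Two beat streams could not be synchronized by IBI matching."""


class UnanalyzableBeatError(PulseDecompError, RuntimeError):
    """A beat where the component pulses could not be located."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class StreamFormatError(PulseDecompError, ValueError):
    """A stream or table file does not conform to the expected format."""
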