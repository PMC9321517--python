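"""Exception types shared across the pipeline stages."""


class SBDAError(Exception):
    """Base class for all package errors."""


class ValidationError(SBDAError, ValueError):
    """An input or configuration violates a documented precondition."""


class ParseError(SBDAError, ValueError):
    """A matrix file could not be parsed; the message names the offending
    line or field."""


class DegenerateSceneError(SBDAError):
    """The slow-time variance is zero in every range bin: a perfectly static
    scene carries no physiological signal and no bin can be selected."""


class NoPeriodicSegmentsError(SBDAError):
    """Every analysis window was rejected by the periodicity gate; there is
    no segment from which to extract a breathing signal."""


class NoRespiratoryComponentError(SBDAError):
    """No intrinsic mode function passed the respiration band-energy
    threshold; the caller may widen the band or lower the threshold
    explicitly."""
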