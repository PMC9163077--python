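"""Exception hierarchy for cavclamp."""


class CavClampError(Exception):
    """Base class for all cavclamp errors."""


class InvalidParameterError(CavClampError, ValueError):
    """A model parameter violates its physical constraints."""


class ProtocolError(CavClampError, ValueError):
    """A voltage protocol is malformed or an override is invalid."""


class StabilityError(CavClampError, ValueError):
    """The integration step is too coarse for the fastest time constant."""


class ParseError(CavClampError, ValueError):
    """A recording file could not be parsed."""


class AnalysisError(CavClampError, ValueError):
    """An analysis operation was applied to unsuitable data."""
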