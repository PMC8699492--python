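"""Exception hierarchy shared by all semmorph modules."""


class SemmorphError(Exception):
    """Base class for all package errors."""


class InputError(SemmorphError):
    """A file could not be read or decoded."""


class ValidationError(SemmorphError, ValueError):
    """A parameter violates its documented domain."""


class DegenerateInputError(SemmorphError):
    """The input is formally valid but carries no usable signal
    (e.g. a zero-variance image offered to an automatic threshold)."""


class MeasurementError(SemmorphError):
    """A per-cell measurement could not be completed; the message
    carries a diagnostic naming the failing cell."""


class CapacityError(SemmorphError):
    """A synthetic field could not accommodate the requested objects."""
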