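"""Exception types shared across the package."""


class FlowscError(Exception):
    """Base class for package errors."""


class FormatError(FlowscError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(FlowscError, ValueError):
    """An in-memory object violates its invariants or a precondition."""
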