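"""Exception hierarchy shared by all pipeline stages."""


class PhosphoscreenError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PhosphoscreenError):
    """A table is missing mandatory columns or is otherwise malformed."""


class ValidationError(PhosphoscreenError):
    """A value violates a data-model invariant (e.g. negative intensity)."""


class InsufficientDataError(PhosphoscreenError):
    """Too few samples/observations to carry out the requested computation."""


class ConfigError(PhosphoscreenError):
    """A simulation or pipeline configuration violates its invariants."""
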