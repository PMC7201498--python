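"""Exception hierarchy shared by all modules."""


class PssmlocError(Exception):
    """Base class for all package errors."""


class ParseError(PssmlocError):
    """A file could not be parsed; message names the offending line/row."""


class ParameterError(PssmlocError, ValueError):
    """A parameter violates an operation's precondition."""


class UsageError(PssmlocError):
    """An operation was called in an invalid state or with mismatched inputs."""


class ValidationError(PssmlocError):
    """Input data violates a documented invariant."""
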