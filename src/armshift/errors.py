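"""Exception types shared across the package."""


class ArmshiftError(Exception):
    """Base class for all package errors."""


class ValidationError(ArmshiftError, ValueError):
    """Input violates a documented precondition or schema."""


class FormatError(ArmshiftError, ValueError):
    """A textual token (arm name, bin label, ...) could not be parsed."""


class DegenerateInputError(ArmshiftError, ValueError):
    """Input sits exactly on a decision boundary where the result is undefined."""
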