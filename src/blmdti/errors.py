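"""Exception hierarchy shared across the package."""


class BlmdtiError(Exception):
    """Base class for all package errors."""


class ValidationError(BlmdtiError):
    """Input data violates a documented contract (bad id, alphabet, class tag...)."""


class ContractError(BlmdtiError):
    """A caller violated an API precondition (mismatched widths, unknown ids...)."""


class ConfigurationError(BlmdtiError):
    """A configuration value is outside its documented range."""


class UndefinedMetricError(BlmdtiError):
    """A metric is requested on data where it is mathematically undefined
    (e.g. AUC with single-class labels). Raised instead of silently
    returning a placeholder value."""


class SmilesParseError(ValidationError):
    """SMILES string rejected.

    ``offset`` is the 0-based character position of the offending token;
    errors detected only at end of input (unclosed parenthesis or ring
    bond) point one past the last character.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (offset {offset})"
        super().__init__(message)
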