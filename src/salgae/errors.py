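"""Exception hierarchy shared across the package."""


class SalgaeError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SalgaeError, ValueError):
    """An input violates a documented precondition (wrong sign, range, units)."""


class ParseError(SalgaeError, ValueError):
    """A delimited-text table could not be interpreted; message names the row."""


class UnderdeterminedError(SalgaeError, ValueError):
    """Too few distinct design points to identify the model parameters."""
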