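"""Exception hierarchy shared across the toolkit."""


class ClamlKitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(ClamlKitError):
    """Raised when an input document cannot be parsed.

    Carries ``line`` when the underlying parser reports one.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class IntegrityError(ClamlKitError):
    """Raised when data is well-formed but violates a structural invariant
    (duplicate codes, cycles, dangling references, duplicate edges...)."""


class CodeFormatError(ClamlKitError):
    """Raised when a classification code does not match the expected shape."""


class VocabularyError(ClamlKitError):
    """Raised when a value falls outside a closed controlled vocabulary."""


class ParameterError(ClamlKitError):
    """Raised for impossible or inconsistent user-supplied parameters."""
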