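"""Exception hierarchy shared across the package."""


class NGNError(Exception):
    """Base class for all package-specific errors."""


class GrammarError(NGNError):
    """Problems with grammar content or structure."""


class GrammarSyntaxError(GrammarError):
    """Malformed grammar-file text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GrammarReferenceError(GrammarError):
    """A rule references a symbol that no rule declares."""


class GrammarValidationError(GrammarError):
    """Grammar invariants violated (indices, duplicate tokens, ...)."""


class NondeterministicGrammarError(GrammarError):
    """Grammar failed the LR determinism check at load time."""


class TokenizationError(NGNError):
    """Unrecognized input at a character offset."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (offset {offset})")


class ParseError(NGNError):
    """Token sequence is not in the grammar's language."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        super().__init__(message)


class DataError(NGNError):
    """Bad dataset content (lengths, missing columns, unparseable rows)."""


class ConfigError(NGNError):
    """Out-of-range or inconsistent run configuration."""


class LibraryMismatchError(NGNError):
    """A network references a weight-layer key the library does not hold."""


class StateError(NGNError):
    """Operation called out of order (e.g. backprop before feedforward)."""


class UndefinedStatisticError(NGNError):
    """A statistic is undefined for the given input (zero variance etc.)."""


class GenerationError(NGNError):
    """The synthetic sampler could not satisfy the request."""


class DesignError(NGNError):
    """Cross-validation design inconsistent with the dataset."""
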