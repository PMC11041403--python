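"""Exception hierarchy shared across the package."""


class CowordcastError(Exception):
    """Base class for all package-specific errors."""


class CorpusFormatError(CowordcastError):
    """Raised when an input corpus file cannot be parsed under the named dialect."""

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (near byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class ConfigurationError(CowordcastError):
    """Raised for invalid configuration values (inverted spans, unknown backends, ...)."""


class MissingEmbeddingError(CowordcastError):
    """Raised when a requested term has no vector in the embedding table."""

    def __init__(self, terms):
        terms = list(terms)
        super().__init__(f"no embedding for term(s): {', '.join(terms)}")
        self.terms = terms


class UnclassifiableTermError(CowordcastError):
    """Raised when a term cannot be assigned a domain (no embedding)."""


class UndefinedSimilarityError(CowordcastError):
    """Raised when cosine similarity is requested for a zero-norm vector."""


class NoHistoryError(CowordcastError):
    """Raised when a forecast is requested without any prior observed bin."""


class UndefinedR2Error(CowordcastError):
    """Raised when R^2 is requested against a zero-variance target."""
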