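"""Exception types shared across the package."""


class MetaphorspaceError(Exception):
    """Base class for all package-specific errors."""


class CorpusDecodingError(MetaphorspaceError):
    """Raw corpus bytes could not be decoded as UTF-8."""

    def __init__(self, byte_offset: int, reason: str = ""):
        self.byte_offset = byte_offset
        super().__init__(
            f"undecodable input at byte offset {byte_offset}"
            + (f": {reason}" if reason else "")
        )


class EmptyCorpusError(MetaphorspaceError):
    """No tokens were found while building a vocabulary."""


class InvalidTableError(MetaphorspaceError):
    """A co-occurrence table violates the preconditions of PMI weighting."""


class OutOfVocabularyError(MetaphorspaceError, KeyError):
    """A requested word is not a row of the PMI matrix."""

    def __init__(self, word: str):
        self.word = word
        super().__init__(f"word not in vocabulary: {word!r}")


class DegenerateSubspaceError(MetaphorspaceError):
    """Dimension selection produced no usable dimensions."""


class DegenerateVectorError(MetaphorspaceError):
    """A zero-length vector where a direction is required (strict mode)."""


class EmbeddingFormatError(MetaphorspaceError):
    """A word2vec-format embedding file is malformed."""


class InsufficientDataError(MetaphorspaceError):
    """Too few rows for the requested statistical operation."""


class ValidationError(MetaphorspaceError):
    """A configuration or synthetic-data spec failed validation."""
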