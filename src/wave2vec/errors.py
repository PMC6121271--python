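"""Exception hierarchy for the wave2vec pipeline."""


class Wave2vecError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(Wave2vecError):
    """A text artifact (signal file, corpus, vector table) is malformed."""


class EmptySignalError(Wave2vecError):
    """A signal file yielded no data rows."""


class SerializationError(Wave2vecError):
    """An object cannot be written in the requested text format."""


class DegenerateDistributionError(Wave2vecError):
    """The pooled delta distribution has zero spread; no quantizer exists."""


class EmptyVocabularyError(Wave2vecError):
    """Frequency filtering removed every token."""


class DivergenceError(Wave2vecError):
    """CBOW training produced a non-finite loss."""

    def __init__(self, epoch: int, learning_rate: float):
        self.epoch = epoch
        self.learning_rate = learning_rate
        super().__init__(
            f"non-finite training loss at epoch {epoch} "
            f"(initial learning rate {learning_rate}); lower the learning rate"
        )


class UnclassifiableError(Wave2vecError):
    """A sequence has no usable vector (all tokens out of vocabulary)."""


class UndefinedSimilarityError(Wave2vecError):
    """Cosine similarity requested against a zero vector."""


class StratificationError(Wave2vecError):
    """A cross-validation fold cannot contain every class."""


class PlacementError(Wave2vecError):
    """Synthetic motifs cannot be placed without overlap."""


class ConfigError(Wave2vecError):
    """A run configuration failed schema validation."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")
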