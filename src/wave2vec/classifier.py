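"""Classification of symbol sequences.

Two classifiers are provided:

* the vector-space classifier — a sequence's vector is the sum of the wave
  vectors of its tokens; each class is modeled by the vector sum over all
  its training sequences; a test sequence is assigned the class whose model
  has the highest cosine similarity.  Only the *direction* of a model vector
  matters, so sum and mean aggregation yield identical decisions;
* a pattern-probability baseline — class-conditional n-gram statistics score
  a sequence by sum(O·S·p(c|pattern))/n, where O is the pattern's occurrence
  count in the sequence, S a length-proportional weight, p(c|pattern)=L/G
  from training counts, and n the token count of the sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .embedding import WaveVectorTable
from .errors import UnclassifiableError, UndefinedSimilarityError, Wave2vecError
from .types import SymbolSequence

__all__ = [
    "SequenceVector",
    "ClassModel",
    "PatternStats",
    "sequence_vector",
    "build_class_model",
    "cosine_similarity",
    "classify",
    "fit_pattern_stats",
    "sequence_class_prob",
    "classify_by_patterns",
]


@dataclass
class SequenceVector:
    """Vector sum of a sequence's token vectors.

    ``degenerate`` is True when no token was found in the table (the vector
    is then zero and the sequence cannot be classified).
    """

    vector: np.ndarray
    n_tokens: int
    n_in_vocab: int

    @property
    def degenerate(self) -> bool:
        return self.n_in_vocab == 0 or not np.any(self.vector)


@dataclass
class ClassModel:
    """A class's summed wave vector; only its direction is meaningful."""

    label: str
    model_vector: np.ndarray
    n_training_sequences: int

    def __post_init__(self) -> None:
        self.model_vector = np.asarray(self.model_vector, dtype=float)
        if not np.all(np.isfinite(self.model_vector)):
            raise Wave2vecError(f"model {self.label!r}: non-finite vector")
        if self.n_training_sequences < 1:
            raise Wave2vecError(f"model {self.label!r}: built from no sequences")


def sequence_vector(seq: SymbolSequence, table: WaveVectorTable) -> SequenceVector:
    """Sum the wave vectors of all tokens; out-of-vocabulary tokens skipped."""
    vec = np.zeros(table.dim)
    n_in = 0
    for tok in seq.tokens:
        if tok in table:
            vec += table.vector(tok)
            n_in += 1
    return SequenceVector(vector=vec, n_tokens=len(seq.tokens), n_in_vocab=n_in)


def build_class_model(
    seqs: list[SymbolSequence], table: WaveVectorTable, label: str
) -> ClassModel:
    """Vector summation over all training sequences of one class."""
    if not seqs:
        raise Wave2vecError(f"class {label!r}: no training sequences")
    total = np.zeros(table.dim)
    for seq in seqs:
        total += sequence_vector(seq, table).vector
    return ClassModel(label=label, model_vector=total, n_training_sequences=len(seqs))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """A·B / (‖A‖‖B‖), in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def classify(
    seq: SymbolSequence,
    models: list[ClassModel],
    table: WaveVectorTable,
) -> tuple[str, dict[str, float]]:
    """Label of the model with maximal cosine similarity, plus all scores.

    Ties break by model list order, so results are deterministic.
    """
    if len(models) < 2:
        raise Wave2vecError("need at least 2 class models")
    sv = sequence_vector(seq, table)
    if sv.degenerate:
        raise UnclassifiableError(
            f"sequence {seq.instance_id!r}: no in-vocabulary tokens, "
            "vector is degenerate"
        )
    scores = {m.label: cosine_similarity(sv.vector, m.model_vector) for m in models}
    best = max(models, key=lambda m: scores[m.label])  # max() keeps first on ties
    return best.label, scores


# ---------------------------------------------------------------------------
# Pattern-probability baseline
# ---------------------------------------------------------------------------


def _ngrams(tokens: list[str], max_len: int) -> Counter[tuple[str, ...]]:
    grams: Counter[tuple[str, ...]] = Counter()
    for n in range(1, max_len + 1):
        for i in range(len(tokens) - n + 1):
            grams[tuple(tokens[i : i + n])] += 1
    return grams


@dataclass
class PatternStats:
    """Training-corpus n-gram counts for the probability baseline.

    ``l_counts[(pattern, class)]`` is L — occurrences of the pattern in
    class-c training sequences; ``g_counts[length]`` is G — total count of
    all patterns of that length over the whole training corpus; the pattern
    weight S(N) = N gives longer patterns proportionally more influence.
    """

    l_counts: dict[tuple[tuple[str, ...], str], int]
    g_counts: dict[int, int]
    classes: list[str]
    max_pattern_len: int

    def pattern_weight(self, length: int) -> float:
        return float(length)

    def pattern_prob(self, pattern: tuple[str, ...], c: str) -> float:
        """p(c | pattern) = L / G for the pattern's length."""
        g = self.g_counts.get(len(pattern), 0)
        if g == 0:
            return 0.0
        return self.l_counts.get((pattern, c), 0) / g


def fit_pattern_stats(
    corpus: list[SymbolSequence], max_pattern_len: int
) -> PatternStats:
    """Count every contiguous n-gram of length 1…max_pattern_len per class."""
    if max_pattern_len < 1:
        raise Wave2vecError("max_pattern_len must be >= 1")
    unlabeled = [s.instance_id for s in corpus if s.label is None]
    if unlabeled:
        raise Wave2vecError(f"unlabeled sequences in training corpus: {unlabeled[:5]}")
    l_counts: dict[tuple[tuple[str, ...], str], int] = {}
    g_counts: dict[int, int] = {n: 0 for n in range(1, max_pattern_len + 1)}
    classes: list[str] = []
    for seq in corpus:
        if seq.label not in classes:
            classes.append(seq.label)
        for pattern, count in _ngrams(seq.tokens, max_pattern_len).items():
            key = (pattern, seq.label)
            l_counts[key] = l_counts.get(key, 0) + count
            g_counts[len(pattern)] += count
    return PatternStats(
        l_counts=l_counts,
        g_counts=g_counts,
        classes=sorted(classes),
        max_pattern_len=max_pattern_len,
    )


def sequence_class_prob(seq: SymbolSequence, stats: PatternStats, c: str) -> float:
    """Score = sum over distinct patterns of O·S·p(c|pattern), divided by n.

    O is the pattern's occurrence count in the sequence, S the length weight,
    and n the number of tokens in the sequence.
    """
    if not seq.tokens:
        raise Wave2vecError(f"sequence {seq.instance_id!r} is empty")
    n = len(seq.tokens)
    score = 0.0
    for pattern, occurrences in _ngrams(seq.tokens, stats.max_pattern_len).items():
        p = stats.pattern_prob(pattern, c)
        if p:
            score += occurrences * stats.pattern_weight(len(pattern)) * p
    return score / n


def classify_by_patterns(seq: SymbolSequence, stats: PatternStats) -> str:
    """argmax over classes of the pattern-probability score.

    Ties break by lexical class order; an all-zero score vector means the
    sequence shares no pattern with any class and is unclassifiable.
    """
    if len(stats.classes) < 2:
        raise Wave2vecError("need at least 2 classes in pattern stats")
    scores = {c: sequence_class_prob(seq, stats, c) for c in stats.classes}
    if all(v == 0.0 for v in scores.values()):
        raise UnclassifiableError(
            f"sequence {seq.instance_id!r}: no pattern seen in any class"
        )
    return max(sorted(scores), key=lambda c: scores[c])
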