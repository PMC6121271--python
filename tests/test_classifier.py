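import itertools

import numpy as np
import pytest

import wave2vec as wv
from wave2vec.classifier import (
    ClassModel,
    build_class_model,
    classify,
    classify_by_patterns,
    cosine_similarity,
    fit_pattern_stats,
    sequence_class_prob,
    sequence_vector,
)
from wave2vec.errors import (
    UnclassifiableError,
    UndefinedSimilarityError,
    Wave2vecError,
)
from wave2vec.types import SymbolSequence

from tests.conftest import random_table


def seq(tokens, iid="s", label=None):
    return SymbolSequence(iid, list(tokens), label=label)


def fixed_table(vectors):
    from wave2vec.embedding import Vocabulary, WaveVectorTable

    vocab = Vocabulary(
        symbols=list(vectors), counts={t: 1 for t in vectors}, min_frequency=1
    )
    return WaveVectorTable(
        vocabulary=vocab, vectors={t: np.array(v, float) for t, v in vectors.items()}
    )


class TestSequenceVector:
    def test_sum_of_token_vectors(self):
        table = fixed_table({"a": [1, 0], "b": [0, 1]})
        sv = sequence_vector(seq(["a", "b"]), table)
        assert sv.vector.tolist() == [1, 1] and not sv.degenerate

    def test_all_oov_is_degenerate_zero(self):
        table = fixed_table({"a": [1, 0]})
        sv = sequence_vector(seq(["x", "y"]), table)
        assert sv.degenerate and not np.any(sv.vector)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, list("abcde"))
        for _ in range(50):
            tokens = [
                "abcde"[i] for i in rng.integers(0, 5, rng.integers(2, 20))
            ]
            shuffled = list(tokens)
            rng.shuffle(shuffled)
            v1 = sequence_vector(seq(tokens), table).vector
            v2 = sequence_vector(seq(shuffled), table).vector
            np.testing.assert_allclose(v1, v2, atol=1e-12)


class TestClassModel:
    def test_sum_of_sequence_vectors(self):
        table = fixed_table({"a": [1, 0], "b": [0, 1]})
        model = build_class_model([seq(["a"]), seq(["b"])], table, "c")
        assert model.model_vector.tolist() == [1, 1]

    def test_single_sequence_model(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, list("abc"))
        s = seq(["a", "b", "c", "a"])
        model = build_class_model([s], table, "c")
        np.testing.assert_allclose(
            model.model_vector, sequence_vector(s, table).vector
        )

    def test_empty_class_rejected(self):
        with pytest.raises(Wave2vecError):
            build_class_model([], fixed_table({"a": [1.0]}), "c")

    def test_sum_vs_mean_aggregation_same_decisions(self):
        """Cosine only sees direction, so sum and mean models must agree."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            table = random_table(rng, list("abcdef"), dim=5)
            classes = {"p": [], "q": []}
            for label in classes:
                for j in range(rng.integers(2, 6)):
                    tokens = [
                        "abcdef"[i]
                        for i in rng.integers(0, 6, rng.integers(3, 15))
                    ]
                    classes[label].append(seq(tokens, f"{label}{j}"))
            sum_models, mean_models = [], []
            for label, seqs in classes.items():
                m = build_class_model(seqs, table, label)
                sum_models.append(m)
                mean_models.append(
                    ClassModel(
                        label=label,
                        model_vector=m.model_vector / len(seqs),
                        n_training_sequences=len(seqs),
                    )
                )
            for _ in range(5):
                tokens = [
                    "abcdef"[i] for i in rng.integers(0, 6, rng.integers(3, 15))
                ]
                t = seq(tokens, "t")
                assert (
                    classify(t, sum_models, table)[0]
                    == classify(t, mean_models, table)[0]
                )


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, -3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_opposite_vectors(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine_similarity(v, -v) == pytest.approx(-1.0, abs=1e-12)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b = rng.normal(size=6), rng.normal(size=6)
            k = float(rng.uniform(0.01, 100))
            assert cosine_similarity(a, b) == pytest.approx(
                cosine_similarity(b, a), abs=1e-12
            )
            assert cosine_similarity(k * a, b) == pytest.approx(
                cosine_similarity(a, b), abs=1e-12
            )

    def test_zero_vector_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestClassify:
    def _models(self):
        return [
            ClassModel(label="A", model_vector=np.array([1.0, 0.0]),
                       n_training_sequences=1),
            ClassModel(label="N", model_vector=np.array([0.0, 1.0]),
                       n_training_sequences=1),
        ]

    def test_nearest_model_wins(self):
        table = fixed_table({"t": [1.0, 0.1]})
        label, scores = classify(seq(["t"]), self._models(), table)
        assert label == "A" and scores["A"] > scores["N"]

    def test_exact_tie_takes_first_model(self):
        table = fixed_table({"t": [1.0, 1.0]})
        label, _ = classify(seq(["t"]), self._models(), table)
        assert label == "A"

    def test_degenerate_sequence_unclassifiable(self):
        table = fixed_table({"t": [1.0, 0.0]})
        with pytest.raises(UnclassifiableError):
            classify(seq(["oov"]), self._models(), table)

    def test_positive_rescaling_never_changes_decision(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            table = random_table(rng, list("abcd"), dim=4)
            models = [
                ClassModel(label=l, model_vector=rng.normal(size=4),
                           n_training_sequences=1)
                for l in ("p", "q", "r")
            ]
            scaled = [
                ClassModel(
                    label=m.label,
                    model_vector=float(rng.uniform(0.01, 50)) * m.model_vector,
                    n_training_sequences=1,
                )
                for m in models
            ]
            tokens = ["abcd"[i] for i in rng.integers(0, 4, 10)]
            t = seq(tokens)
            assert classify(t, models, table)[0] == classify(t, scaled, table)[0]


# ---------------------------------------------------------------------------
# pattern-probability baseline
# ---------------------------------------------------------------------------


def oracle_score(tokens, corpus, c, max_len):
    """Independent brute-force scoring by direct corpus scans."""

    def occurrences(hay, pat):
        return sum(
            1
            for i in range(len(hay) - len(pat) + 1)
            if tuple(hay[i : i + len(pat)]) == pat
        )

    patterns = {
        tuple(tokens[i : i + m])
        for m in range(1, max_len + 1)
        for i in range(len(tokens) - m + 1)
    }
    total = 0.0
    for pat in patterns:
        o = occurrences(tokens, pat)
        s = len(pat)
        l = sum(occurrences(sq.tokens, pat) for sq in corpus if sq.label == c)
        g = sum(
            max(0, len(sq.tokens) - len(pat) + 1) for sq in corpus
        )
        total += o * s * (l / g if g else 0.0)
    return total / len(tokens)


class TestPatternStats:
    def test_worked_example(self):
        stats = fit_pattern_stats([seq("ABA", label="c")], max_pattern_len=1)
        assert stats.l_counts[(("A",), "c")] == 2
        assert stats.g_counts[1] == 3
        assert stats.pattern_prob(("A",), "c") == pytest.approx(2 / 3)

    def test_unseen_pattern_probability_zero(self):
        stats = fit_pattern_stats([seq("ABA", label="c")], max_pattern_len=2)
        assert stats.pattern_prob(("Z",), "c") == 0.0

    def test_counts_conserved_across_classes(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            corpus = [
                seq(
                    ["XYZ"[i] for i in rng.integers(0, 3, rng.integers(2, 12))],
                    f"s{j}",
                    label=("c1", "c2")[j % 2],
                )
                for j in range(8)
            ]
            stats = fit_pattern_stats(corpus, max_pattern_len=3)
            for pattern in {p for p, _ in stats.l_counts}:
                total_l = sum(
                    stats.l_counts.get((pattern, c), 0) for c in stats.classes
                )
                direct = sum(
                    sum(
                        1
                        for i in range(len(sq.tokens) - len(pattern) + 1)
                        if tuple(sq.tokens[i : i + len(pattern)]) == pattern
                    )
                    for sq in corpus
                )
                assert total_l == direct

    def test_weight_proportional_to_length(self):
        stats = fit_pattern_stats([seq("AB", label="c")], max_pattern_len=4)
        assert [stats.pattern_weight(n) for n in (1, 2, 3, 4)] == [1, 2, 3, 4]


class TestSequenceClassProb:
    CORPUS = [
        seq("ABAC", "t0", label="c1"),
        seq("BBCA", "t1", label="c1"),
        seq("CCAB", "t2", label="c2"),
        seq("ACBA", "t3", label="c2"),
    ]

    def test_single_token_certain_pattern(self):
        stats = fit_pattern_stats([seq("A", label="c")], max_pattern_len=1)
        assert sequence_class_prob(seq("A"), stats, "c") == pytest.approx(1.0)

    def test_foreign_sequence_scores_zero(self):
        stats = fit_pattern_stats(self.CORPUS, max_pattern_len=2)
        assert sequence_class_prob(seq("ZZZ"), stats, "c1") == 0.0

    def test_matches_enumeration_oracle_exhaustively(self):
        """Exact agreement on every sequence of length <= 6 over {A,B,C}."""
        stats = fit_pattern_stats(self.CORPUS, max_pattern_len=3)
        for length in range(1, 7):
            for tokens in itertools.product("ABC", repeat=length):
                s = seq(tokens)
                for c in ("c1", "c2"):
                    got = sequence_class_prob(s, stats, c)
                    want = oracle_score(list(tokens), self.CORPUS, c, 3)
                    assert got == pytest.approx(want, abs=1e-12), (tokens, c)

    def test_empty_sequence_rejected(self):
        stats = fit_pattern_stats(self.CORPUS, max_pattern_len=2)
        with pytest.raises(Wave2vecError):
            sequence_class_prob(seq([]), stats, "c1")


class TestClassifyByPatterns:
    def test_forced_argmax(self):
        corpus = [seq("AAA", "a", label="c1"), seq("BBB", "b", label="c2")]
        stats = fit_pattern_stats(corpus, max_pattern_len=2)
        assert classify_by_patterns(seq("AA"), stats) == "c1"

    def test_symmetric_corpus_breaks_ties_lexically(self):
        corpus = [seq("AB", "a", label="z"), seq("AB", "b", label="y")]
        stats = fit_pattern_stats(corpus, max_pattern_len=1)
        assert classify_by_patterns(seq("AB"), stats) == "y"

    def test_unseen_everywhere_unclassifiable(self):
        corpus = [seq("AB", "a", label="c1"), seq("BA", "b", label="c2")]
        stats = fit_pattern_stats(corpus, max_pattern_len=1)
        with pytest.raises(UnclassifiableError):
            classify_by_patterns(seq("Z"), stats)

    def test_mostly_agrees_with_vector_classifier(self):
        cfg = wv.default_config(n_per_class=60, seed=5)
        dataset, _ = wv.generate_dataset(cfg)
        spec = wv.fit_quantizer(
            [wv.delta_encode(s) for s in dataset.instances], base_n=16
        )
        seqs = [wv.encode_signal(s, spec) for s in dataset.instances]
        per_class = len(seqs) // 2
        cut = 2 * per_class // 3
        train = seqs[:cut] + seqs[per_class : per_class + cut]
        test = seqs[cut:per_class] + seqs[per_class + cut :]
        stats = fit_pattern_stats(train, max_pattern_len=2)
        table = wv.train_cbow(train, wv.CBOWConfig.from_window_param(10, seed=1))
        models = [
            build_class_model([s for s in train if s.label == c], table, c)
            for c in sorted(dataset.classes)
        ]
        agree = sum(
            classify(s, models, table)[0] == classify_by_patterns(s, stats)
            for s in test
        )
        assert agree / len(test) >= 0.8
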