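"""CBOW wave embedding: learn a dense vector per alphabet symbol.

The continuous-bag-of-words model predicts a target symbol from the average
of its context symbols' vectors.  For a window of length ``t`` (odd), the
center symbol is the target and up to ``(t-1)/2`` symbols on each side are
the context; the window slides one symbol at a time, so every position in a
sequence contributes one training pair (contexts are truncated at sequence
boundaries, and windows never cross instance boundaries).

Forward pass: the context rows of the V×N input (projection) matrix are
averaged, multiplied by the N×V output matrix, and softmaxed over the
vocabulary; the loss is cross-entropy against the target.  Parameters are
updated by plain SGD.  Vocabulary sizes here are tiny (V ≤ base_n ≤ 1024),
so the full softmax is tractable and no sampling approximation is used.
The learned wave vectors are the rows of the input matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, EmptyVocabularyError, Wave2vecError
from .types import SymbolSequence

__all__ = [
    "Vocabulary",
    "CBOWConfig",
    "WaveVectorTable",
    "build_vocab",
    "make_training_windows",
    "train_cbow",
]


@dataclass
class Vocabulary:
    """Retained tokens (count >= min_frequency) with stable indices."""

    symbols: list[str]
    counts: dict[str, int]
    min_frequency: int = 1
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.symbols) != len(set(self.symbols)):
            raise Wave2vecError("vocabulary symbols must be unique")
        self.index = {s: i for i, s in enumerate(self.symbols)}

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, token: str) -> bool:
        return token in self.index


@dataclass(frozen=True)
class CBOWConfig:
    """Training hyperparameters.

    ``window_t`` is the total sliding-window length and must be odd (the
    center is the target): context per side = (window_t - 1) / 2.  Use
    :meth:`from_window_param` to accept an even "window" setting, which is
    interpreted as the context size per side (window 10 → t = 21).
    """

    window_t: int = 7
    dim_n: int = 50
    epochs: int = 3
    learning_rate: float = 0.05
    seed: int = 0
    min_frequency: int = 1

    def __post_init__(self) -> None:
        if self.window_t < 3 or self.window_t % 2 == 0:
            raise Wave2vecError(f"window_t must be odd and >= 3, got {self.window_t}")
        if self.dim_n < 1 or self.epochs < 1:
            raise Wave2vecError("dim_n and epochs must be positive")
        if not self.learning_rate > 0:
            raise Wave2vecError("learning_rate must be positive")

    @property
    def context_per_side(self) -> int:
        return (self.window_t - 1) // 2

    @classmethod
    def from_window_param(cls, window: int, **kwargs) -> "CBOWConfig":
        """Odd ``window`` is the full width t; even ``window`` is per-side."""
        t = window if window % 2 == 1 else 2 * window + 1
        return cls(window_t=t, **kwargs)


@dataclass
class WaveVectorTable:
    """The wave embedding: one dense vector per retained symbol."""

    vocabulary: Vocabulary
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [s for s in self.vocabulary.symbols if s not in self.vectors]
        if missing:
            raise Wave2vecError(f"vectors missing for {missing[:5]}")
        for tok, vec in self.vectors.items():
            self.vectors[tok] = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(self.vectors[tok])):
                raise Wave2vecError(f"non-finite vector for {tok!r}")

    def tokens(self) -> list[str]:
        return list(self.vocabulary.symbols)

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    @property
    def dim(self) -> int:
        first = next(iter(self.vectors.values()), np.empty(0))
        return int(first.size)


def build_vocab(corpus: list[SymbolSequence], min_frequency: int = 1) -> Vocabulary:
    """Count tokens over the corpus and drop those below min_frequency.

    Symbol order is first-appearance order, which makes vocabulary indices
    deterministic for a given corpus.
    """
    if not corpus:
        raise Wave2vecError("corpus is empty")
    counts: Counter[str] = Counter()
    order: list[str] = []
    seen: set[str] = set()
    for seq in corpus:
        for tok in seq.tokens:
            counts[tok] += 1
            if tok not in seen:
                seen.add(tok)
                order.append(tok)
    retained = [t for t in order if counts[t] >= min_frequency]
    if not retained:
        raise EmptyVocabularyError(
            f"min_frequency={min_frequency} removed all {len(counts)} token types"
        )
    return Vocabulary(
        symbols=retained,
        counts={t: counts[t] for t in retained},
        min_frequency=min_frequency,
    )


def make_training_windows(
    seq: SymbolSequence, window_t: int, vocab: Vocabulary | None = None
) -> list[tuple[list[str], str]]:
    """One (context, target) pair per token position.

    Tokens outside ``vocab`` (if given) are removed before windowing, so
    frequency-filtered symbols neither serve as targets nor as contexts.
    Contexts are truncated at the sequence boundaries.
    """
    if window_t < 3 or window_t % 2 == 0:
        raise Wave2vecError(f"window_t must be odd and >= 3, got {window_t}")
    half = (window_t - 1) // 2
    tokens = (
        [t for t in seq.tokens if t in vocab] if vocab is not None else seq.tokens
    )
    pairs: list[tuple[list[str], str]] = []
    for i, target in enumerate(tokens):
        context = tokens[max(0, i - half) : i] + tokens[i + 1 : i + 1 + half]
        pairs.append((context, target))
    return pairs


def _softmax(u: np.ndarray) -> np.ndarray:
    e = np.exp(u - u.max())
    return e / e.sum()


def cbow_loss_and_grads(
    w_in: np.ndarray,
    w_out: np.ndarray,
    context_idx: np.ndarray,
    target: int,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Cross-entropy loss and analytic gradients for one training pair.

    Returns (loss, grad wrt the averaged context rows of w_in, grad w_out,
    softmax probabilities).  Exposed so the gradients can be checked against
    numerical differentiation.
    """
    h = w_in[context_idx].mean(axis=0)
    p = _softmax(h @ w_out)
    loss = -float(np.log(p[target] + 1e-300))
    e = p.copy()
    e[target] -= 1.0
    grad_h = w_out @ e
    grad_w_out = np.outer(h, e)
    return loss, grad_h, grad_w_out, p


def _sgd_python(
    w_in: np.ndarray,
    w_out: np.ndarray,
    targets: np.ndarray,
    ctx_flat: np.ndarray,
    ctx_off: np.ndarray,
    order: np.ndarray,
    lr0: float,
) -> tuple[np.ndarray, int]:
    """Reference SGD loop in plain numpy; returns (epoch losses, bad epoch).

    ``order`` is an (epochs, n_windows) matrix of visiting orders.  A bad
    epoch >= 0 signals a non-finite loss at that epoch.
    """
    epochs, n_windows = order.shape
    denom = max(epochs * n_windows - 1, 1)
    update = 0
    losses = np.zeros(epochs)
    for epoch in range(epochs):
        loss_sum = 0.0
        for w in order[epoch]:
            ctx = ctx_flat[ctx_off[w] : ctx_off[w + 1]]
            t = targets[w]
            loss, grad_h, grad_w_out, _ = cbow_loss_and_grads(w_in, w_out, ctx, t)
            if not np.isfinite(loss):
                return losses, epoch
            lr = lr0 * (1.0 - (1.0 - 1e-4) * update / denom)
            w_out -= lr * grad_w_out
            np.subtract.at(w_in, ctx, (lr / ctx.size) * grad_h)
            loss_sum += loss
            update += 1
        losses[epoch] = loss_sum / n_windows
    return losses, -1


def _make_sgd_compiled():
    """Numba-compiled twin of :func:`_sgd_python` (same math, same order)."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a soft dependency
        return None

    @njit(cache=False, fastmath=False)
    def _sgd(w_in, w_out, targets, ctx_flat, ctx_off, order, lr0):
        epochs, n_windows = order.shape
        v = w_out.shape[1]
        n = w_in.shape[1]
        denom = max(epochs * n_windows - 1, 1)
        h = np.zeros(n)
        u = np.zeros(v)
        grad_h = np.zeros(n)
        losses = np.zeros(epochs)
        update = 0
        for epoch in range(epochs):
            loss_sum = 0.0
            for k in range(n_windows):
                w = order[epoch, k]
                lo, hi = ctx_off[w], ctx_off[w + 1]
                csize = hi - lo
                t = targets[w]
                for i in range(n):
                    s = 0.0
                    for c in range(lo, hi):
                        s += w_in[ctx_flat[c], i]
                    h[i] = s / csize
                for j in range(v):
                    s = 0.0
                    for i in range(n):
                        s += h[i] * w_out[i, j]
                    u[j] = s
                umax = u[0]
                for j in range(1, v):
                    if u[j] > umax:
                        umax = u[j]
                z = 0.0
                for j in range(v):
                    u[j] = np.exp(u[j] - umax)
                    z += u[j]
                for j in range(v):
                    u[j] /= z  # u now holds softmax probabilities
                loss = -np.log(u[t] + 1e-300)
                if not np.isfinite(loss):
                    return losses, epoch
                u[t] -= 1.0  # u now holds the output error e
                lr = lr0 * (1.0 - (1.0 - 1e-4) * update / denom)
                for i in range(n):
                    s = 0.0
                    for j in range(v):
                        s += w_out[i, j] * u[j]
                    grad_h[i] = s
                for i in range(n):
                    hi_lr = lr * h[i]
                    for j in range(v):
                        w_out[i, j] -= hi_lr * u[j]
                g = lr / csize
                for c in range(lo, hi):
                    row = ctx_flat[c]
                    for i in range(n):
                        w_in[row, i] -= g * grad_h[i]
                loss_sum += loss
                update += 1
            losses[epoch] = loss_sum / n_windows
        return losses, -1

    return _sgd


_SGD_COMPILED = _make_sgd_compiled()


def train_cbow(
    corpus: list[SymbolSequence],
    config: CBOWConfig,
    *,
    backend: str = "auto",
) -> WaveVectorTable:
    """Train the CBOW model by SGD and return the input-matrix rows.

    The input matrix is initialized uniformly in [-0.5/N, 0.5/N] from the
    seeded generator; the output matrix starts at zero.  The learning rate
    decays linearly from its start value to 1e-4 of it across all updates.
    Identical seed + corpus + config gives a bit-identical table.

    ``backend`` selects the inner loop: "numba" (compiled), "python"
    (reference numpy loop), or "auto" (compiled when available).  Both loops
    apply the same updates in the same order.
    """
    vocab = build_vocab(corpus, config.min_frequency)
    v, n = len(vocab), config.dim_n

    targets: list[int] = []
    ctx_flat: list[int] = []
    ctx_off = [0]
    for seq in corpus:
        for context, target in make_training_windows(seq, config.window_t, vocab):
            if not context:  # single-token sequence: nothing to predict from
                continue
            targets.append(vocab.index[target])
            ctx_flat.extend(vocab.index[c] for c in context)
            ctx_off.append(len(ctx_flat))
    if not targets:
        raise Wave2vecError("no training windows with non-empty context")
    targets_a = np.asarray(targets, dtype=np.int64)
    ctx_flat_a = np.asarray(ctx_flat, dtype=np.int64)
    ctx_off_a = np.asarray(ctx_off, dtype=np.int64)

    rng = np.random.default_rng(config.seed)
    w_in = rng.uniform(-0.5 / n, 0.5 / n, size=(v, n))
    w_out = np.zeros((n, v))
    n_windows = targets_a.size
    order = np.stack(
        [rng.permutation(n_windows) for _ in range(config.epochs)]
    ).astype(np.int64)

    if backend == "auto":
        sgd = _SGD_COMPILED if _SGD_COMPILED is not None else _sgd_python
    elif backend == "numba":
        if _SGD_COMPILED is None:
            raise Wave2vecError("numba backend requested but numba is unavailable")
        sgd = _SGD_COMPILED
    elif backend == "python":
        sgd = _sgd_python
    else:
        raise Wave2vecError(f"unknown backend {backend!r}")
    losses, bad_epoch = sgd(
        w_in, w_out, targets_a, ctx_flat_a, ctx_off_a, order, config.learning_rate
    )
    if bad_epoch >= 0:
        raise DivergenceError(epoch=int(bad_epoch), learning_rate=config.learning_rate)

    table = WaveVectorTable(
        vocabulary=vocab,
        vectors={tok: w_in[vocab.index[tok]].copy() for tok in vocab.symbols},
    )
    table.epoch_losses = [float(x) for x in losses]  # training diagnostics
    return table
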