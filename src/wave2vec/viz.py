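"""Similarity-matrix visualization and discriminative-pattern identification.

Wave vectors from two separately trained tables live in different vector
spaces, so their raw vectors must never be compared directly.  What *is*
comparable across models is each model's internal structure: the square
matrix of cosine similarities between all alphabet symbols' vectors.  Axes
are ordered from the greatest-drop symbol to the greatest-rise symbol
(D(max)…D01, U00, U01…U(max)) so the bottom-left of a heat map holds strong
drops and the top-right strong rises.

The elementwise difference of two class models' similarity matrices ("XOR")
highlights symbol pairs whose clustering behavior differs between classes;
the top-ranked pairs can be decoded back to amplitude-change intervals via
the quantizer spec, identifying the discriminating wavelet patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifier import cosine_similarity
from .embedding import WaveVectorTable
from .encoder import QuantizerSpec
from .errors import Wave2vecError

__all__ = [
    "SimilarityMatrix",
    "similarity_matrix",
    "matrix_difference",
    "top_divergent_pairs",
    "render_heatmap",
    "write_matrix_tsv",
]


@dataclass
class SimilarityMatrix:
    """Square symbol-by-symbol matrix with its axis ordering."""

    symbols: list[str]
    values: np.ndarray
    source_model: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.symbols)
        if self.values.shape != (n, n):
            raise Wave2vecError(
                f"matrix shape {self.values.shape} != ({n}, {n}) symbols"
            )


def similarity_matrix(
    table: WaveVectorTable, ordering: list[str], source_model: str = ""
) -> SimilarityMatrix:
    """Pairwise cosine similarities between the ordered symbols' vectors."""
    missing = [s for s in ordering if s not in table]
    if missing:
        raise Wave2vecError(f"symbols missing from table: {missing[:10]}")
    vecs = np.stack([table.vector(s) for s in ordering])
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        zero = ordering[int(np.argmax(norms == 0))]
        raise Wave2vecError(f"symbol {zero!r} has a zero vector")
    normalized = vecs / norms[:, None]
    values = np.clip(normalized @ normalized.T, -1.0, 1.0)
    # enforce exact symmetry and unit diagonal against float round-off
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        symbols=list(ordering), values=values, source_model=source_model
    )


def matrix_difference(
    m1: SimilarityMatrix,
    m2: SimilarityMatrix,
    mode: str = "absdiff",
    binarize_threshold: float | None = None,
) -> SimilarityMatrix:
    """Elementwise difference of two similarity matrices.

    ``absdiff`` (default): |M1 - M2|, in [0, 2].  ``binary``: threshold each
    matrix, then logical XOR — the literal reading of "XOR" for users who
    want a hard mask; requires ``binarize_threshold``.
    """
    if m1.symbols != m2.symbols:
        raise Wave2vecError("matrices have different symbol orderings")
    if mode == "absdiff":
        values = np.abs(m1.values - m2.values)
    elif mode == "binary":
        if binarize_threshold is None:
            raise Wave2vecError("binary mode requires binarize_threshold")
        values = np.logical_xor(
            m1.values >= binarize_threshold, m2.values >= binarize_threshold
        ).astype(float)
    else:
        raise Wave2vecError(f"unknown mode {mode!r}")
    name = f"diff({m1.source_model},{m2.source_model})"
    return SimilarityMatrix(symbols=list(m1.symbols), values=values, source_model=name)


def top_divergent_pairs(
    mdiff: SimilarityMatrix, k: int, spec: QuantizerSpec | None = None
) -> list[dict]:
    """Top-k upper-triangle entries by score, ties by (row, col) order.

    With a quantizer spec, each symbol is decoded to the z-score interval of
    amplitude change it stands for, identifying the actual wavelet patterns.
    """
    if k < 1:
        raise Wave2vecError("k must be >= 1")
    n = len(mdiff.symbols)
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size
    if k > n_pairs:
        warnings.warn(
            f"k={k} exceeds {n_pairs} symbol pairs; returning all pairs",
            stacklevel=2,
        )
        k = n_pairs
    scores = mdiff.values[iu, ju]
    # stable sort on -score keeps (row, col) order among ties
    order = np.argsort(-scores, kind="stable")[:k]
    out = []
    for o in order:
        i, j = int(iu[o]), int(ju[o])
        row = {
            "symbol_i": mdiff.symbols[i],
            "symbol_j": mdiff.symbols[j],
            "score": float(scores[o]),
        }
        if spec is not None:
            row["interval_i"] = spec.symbol_interval(mdiff.symbols[i])
            row["interval_j"] = spec.symbol_interval(mdiff.symbols[j])
        out.append(row)
    return out


def render_heatmap(
    matrix: SimilarityMatrix,
    path: str | Path,
    vmin: float = -1.0,
    vmax: float = 1.0,
    title: str | None = None,
) -> Path:
    """Write a blue-to-red heat map (PNG or SVG, by file extension).

    Color limits default to the similarity range [-1, 1]; pass (0, 2) for
    absolute-difference matrices so figures stay comparable across runs.
    SVG output is byte-deterministic for identical matrix and config.
    """
    import matplotlib

    matplotlib.rcParams["svg.hashsalt"] = "wave2vec"
    import matplotlib.pyplot as plt

    path = Path(path)
    n = len(matrix.symbols)
    fig, ax = plt.subplots(figsize=(8, 7))
    try:
        # origin='lower' puts the first symbol (greatest drop) bottom-left
        im = ax.imshow(
            matrix.values, cmap="bwr", vmin=vmin, vmax=vmax, origin="lower"
        )
        step = max(1, n // 16)
        ticks = np.arange(0, n, step)
        ax.set_xticks(ticks)
        ax.set_yticks(ticks)
        ax.set_xticklabels(
            [matrix.symbols[i] for i in ticks], rotation=90, fontsize=7
        )
        ax.set_yticklabels([matrix.symbols[i] for i in ticks], fontsize=7)
        ax.set_title(title or matrix.source_model or "similarity matrix")
        fig.colorbar(im, ax=ax)
        fig.savefig(path, metadata=_deterministic_metadata(path))
    finally:
        plt.close(fig)
    return path


def _deterministic_metadata(path: Path) -> dict | None:
    suffix = path.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None


def write_matrix_tsv(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Symbols as header row and first column, values tab-separated."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["", *matrix.symbols]) + "\n")
        for sym, row in zip(matrix.symbols, matrix.values):
            fh.write(sym + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
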