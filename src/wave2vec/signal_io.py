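"""Text I/O for signals, labels, symbol corpora and vector tables.

All artifacts are plain UTF-8 text with ``\\n`` line endings so that runs are
diffable and reproducible bit-exactly:

* per-instance signal files — one value per line by default; the column
  layout is configurable through :class:`SignalDialect` because trial files
  in the wild range from bare value columns to four-column
  ``trial channel sample value`` layouts;
* labels manifest — TSV of ``instance_id<TAB>class``;
* symbol corpus — one instance per line, ``instance_id token token ...``;
* vector table — word2vec text format: header ``V N`` then one
  ``token v1 ... vN`` row per symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptySignalError, FormatError, SerializationError
from .types import LabeledDataset, RawSignal, SymbolSequence

__all__ = [
    "SignalDialect",
    "read_instance_file",
    "write_instance_file",
    "read_labels_manifest",
    "write_labels_manifest",
    "read_dataset",
    "write_symbol_corpus",
    "read_symbol_corpus",
    "write_vector_table",
    "read_vector_table",
]


@dataclass(frozen=True)
class SignalDialect:
    """Column layout of a per-instance signal text file.

    ``value_column`` indexes the amplitude field after splitting on
    ``delimiter`` (``None`` = any whitespace).  If ``channel_column`` is set,
    only rows whose channel field equals ``channel`` are retained — the usual
    way single-channel analyses (e.g. channel CP6) consume multi-channel
    trial files.  If ``sample_index_column`` is set, retained rows are sorted
    by that integer field; otherwise file order is kept.
    """

    comment_prefix: str = "#"
    delimiter: str | None = None
    value_column: int = 0
    channel_column: int | None = None
    channel: str | None = None
    sample_index_column: int | None = None


#: Default layout: one amplitude per line, '#' comments.
VALUE_ONLY = SignalDialect()


def read_instance_file(
    path: str | Path,
    dialect: SignalDialect = VALUE_ONLY,
    *,
    instance_id: str | None = None,
    sampling_rate_hz: float = 256.0,
    label: str | None = None,
) -> RawSignal:
    """Parse one signal instance from a text file.

    Every line is either a comment/blank (skipped), a row for another channel
    (filtered when the dialect selects a channel), or a data row; anything
    else raises :class:`FormatError` naming the line, so no data row is ever
    silently dropped.
    """
    path = Path(path)
    rows: list[tuple[int, float]] = []
    n_lines = n_skipped = n_filtered = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            n_lines += 1
            stripped = line.strip()
            if not stripped or stripped.startswith(dialect.comment_prefix):
                n_skipped += 1
                continue
            fields = stripped.split(dialect.delimiter)
            if dialect.channel_column is not None and dialect.channel is not None:
                try:
                    chan = fields[dialect.channel_column]
                except IndexError:
                    raise FormatError(
                        f"{path}:{lineno}: missing channel column "
                        f"{dialect.channel_column}"
                    ) from None
                if chan != dialect.channel:
                    n_filtered += 1
                    continue
            try:
                value = float(fields[dialect.value_column])
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"{path}:{lineno}: cannot parse value column "
                    f"{dialect.value_column} from {stripped!r}"
                ) from exc
            if dialect.sample_index_column is not None:
                try:
                    idx = int(fields[dialect.sample_index_column])
                except (IndexError, ValueError) as exc:
                    raise FormatError(
                        f"{path}:{lineno}: cannot parse sample index column "
                        f"{dialect.sample_index_column}"
                    ) from exc
            else:
                idx = len(rows)
            rows.append((idx, value))
    assert len(rows) + n_skipped + n_filtered == n_lines
    if not rows:
        raise EmptySignalError(f"{path}: no data rows")
    rows.sort(key=lambda r: r[0])
    return RawSignal(
        instance_id=instance_id if instance_id is not None else path.stem,
        channel=dialect.channel or "",
        samples=np.array([v for _, v in rows]),
        sampling_rate_hz=sampling_rate_hz,
        label=label,
    )


def write_instance_file(signal: RawSignal, path: str | Path) -> None:
    """Write a signal in the default value-per-line dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# instance {signal.instance_id} channel {signal.channel or '-'} "
                 f"rate {signal.sampling_rate_hz:g} Hz\n")
        for v in signal.samples:
            fh.write(f"{float(v)!r}\n")


def read_labels_manifest(path: str | Path) -> dict[str, str]:
    """Read a TSV of ``instance_id<TAB>class``."""
    labels: dict[str, str] = {}
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            labels[parts[0]] = parts[1]
    return labels


def write_labels_manifest(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for instance_id in labels:
            fh.write(f"{instance_id}\t{labels[instance_id]}\n")


def read_dataset(
    data_dir: str | Path,
    labels_path: str | Path,
    dialect: SignalDialect = VALUE_ONLY,
    *,
    sampling_rate_hz: float = 256.0,
    suffix: str = ".txt",
) -> LabeledDataset:
    """Load every ``<instance_id><suffix>`` named in the labels manifest."""
    labels = read_labels_manifest(labels_path)
    data_dir = Path(data_dir)
    instances = [
        read_instance_file(
            data_dir / f"{iid}{suffix}",
            dialect,
            instance_id=iid,
            sampling_rate_hz=sampling_rate_hz,
            label=lab,
        )
        for iid, lab in labels.items()
    ]
    return LabeledDataset(instances=instances, classes=set(labels.values()))


def write_symbol_corpus(seqs: list[SymbolSequence], path: str | Path) -> None:
    """One instance per line: ``instance_id token token ...``."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for seq in seqs:
            for tok in seq.tokens:
                if not tok or any(c.isspace() for c in tok):
                    raise SerializationError(
                        f"instance {seq.instance_id!r}: token {tok!r} contains "
                        "whitespace and cannot be serialized"
                    )
            if any(c.isspace() for c in seq.instance_id):
                raise SerializationError(
                    f"instance_id {seq.instance_id!r} contains whitespace"
                )
            fh.write(" ".join([seq.instance_id, *seq.tokens]) + "\n")


def read_symbol_corpus(path: str | Path) -> list[SymbolSequence]:
    seqs: list[SymbolSequence] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            seqs.append(SymbolSequence(instance_id=fields[0], tokens=fields[1:]))
    return seqs


def write_vector_table(table, path: str | Path) -> None:
    """Write a vector table in word2vec text format (header ``V N``)."""
    from .embedding import WaveVectorTable  # local import: avoid cycle at load

    assert isinstance(table, WaveVectorTable)
    tokens = table.tokens()
    dims = {len(table.vector(t)) for t in tokens}
    if len(dims) > 1:
        raise SerializationError(f"inconsistent vector dimensions: {sorted(dims)}")
    dim = dims.pop() if dims else 0
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(tokens)} {dim}\n")
        for tok in tokens:
            vec = table.vector(tok)
            fh.write(tok + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def read_vector_table(path: str | Path):
    from .embedding import Vocabulary, WaveVectorTable

    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}:1: expected header 'V N'")
        try:
            n_tokens, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError(f"{path}:1: non-integer header fields") from exc
        tokens: list[str] = []
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            tok, values = fields[0], fields[1:]
            if len(values) != dim:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(values)} values, header says {dim}"
                )
            tokens.append(tok)
            vectors[tok] = np.array([float(v) for v in values])
    if len(tokens) != n_tokens:
        raise FormatError(
            f"{path}: header declares {n_tokens} rows, found {len(tokens)}"
        )
    vocab = Vocabulary(
        symbols=tokens, counts={t: 1 for t in tokens}, min_frequency=1
    )
    return WaveVectorTable(vocabulary=vocab, vectors=vectors)
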