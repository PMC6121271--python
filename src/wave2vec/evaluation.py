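"""Cross-validation harness, metrics, and the base-number parameter sweep.

Evaluation follows the diagnosis framing: one class is designated positive
(the disease class) and precision, recall and F1 are computed from pooled
fold counts.  F1 is the primary metric — with imbalanced classes, accuracy
alone is misleading (the accuracy paradox) — but accuracy is reported too.

Folds are stratified by class so every fold contains both classes even with
imbalanced data, and all fitting (quantizer, CBOW table, class models) uses
only the training portion of each fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier import build_class_model, classify
from .embedding import CBOWConfig, train_cbow
from .encoder import EncoderConfig, delta_encode, downsample, encode_signal, fit_quantizer
from .errors import StratificationError, Wave2vecError
from .types import LabeledDataset, RawSignal

__all__ = [
    "FoldCounts",
    "EvalReport",
    "DEFAULT_BASE_N_LIST",
    "kfold_split",
    "metrics",
    "run_cv",
    "sweep_base_n",
]

logger = logging.getLogger("wave2vec")

#: The 13 encoding base numbers of the reference parameter sweep.
DEFAULT_BASE_N_LIST = [8, 16, 32, 48, 64, 96, 128, 192, 256, 384, 512, 768, 1024]


@dataclass
class FoldCounts:
    """Confusion counts for one fold (positive class vs. rest)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise Wave2vecError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "FoldCounts") -> "FoldCounts":
        return FoldCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )


def metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = their harmonic mean.

    Any 0/0 denominator yields 0 for that metric (logged as a warning).
    """
    if min(tp, fp, fn) < 0:
        raise Wave2vecError("counts must be non-negative")
    if tp + fp == 0:
        logger.warning("precision 0/0 -> 0 (no positive predictions)")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("recall 0/0 -> 0 (no positive instances)")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


@dataclass
class EvalReport:
    """Per-fold and pooled confusion counts plus derived metrics.

    All metrics are recomputable from the stored counts; ``pooled_*``
    properties do exactly that, so the report can never disagree with its
    own counts.
    """

    fold_counts: list[FoldCounts]
    positive_class: str
    config: dict = field(default_factory=dict)

    @property
    def pooled(self) -> FoldCounts:
        total = FoldCounts()
        for fc in self.fold_counts:
            total = total + fc
        return total

    @property
    def pooled_precision(self) -> float:
        p = self.pooled
        return metrics(p.tp, p.fp, p.fn)[0]

    @property
    def pooled_recall(self) -> float:
        p = self.pooled
        return metrics(p.tp, p.fp, p.fn)[1]

    @property
    def pooled_f1(self) -> float:
        p = self.pooled
        return metrics(p.tp, p.fp, p.fn)[2]

    @property
    def pooled_accuracy(self) -> float:
        p = self.pooled
        return (p.tp + p.tn) / p.total if p.total else 0.0

    def to_rows(self) -> list[dict]:
        """One dict per fold plus a pooled row, for TSV export."""
        rows = []
        for i, fc in enumerate([*self.fold_counts, self.pooled]):
            pr, rc, f1 = metrics(fc.tp, fc.fp, fc.fn)
            rows.append(
                {
                    "fold": i if i < len(self.fold_counts) else "pooled",
                    "tp": fc.tp,
                    "fp": fc.fp,
                    "fn": fc.fn,
                    "tn": fc.tn,
                    "precision": pr,
                    "recall": rc,
                    "f1": f1,
                    "accuracy": (fc.tp + fc.tn) / fc.total if fc.total else 0.0,
                }
            )
        return rows


def kfold_split(
    dataset: LabeledDataset, k: int = 10, seed: int = 0
) -> list[list[int]]:
    """Stratified k-fold partition; returns k disjoint lists of indices.

    Instances of each class are shuffled with the seeded generator and dealt
    round-robin across folds, so folds are as class-balanced as arithmetic
    allows and the same seed always reproduces the same folds.
    """
    n = len(dataset)
    if k < 2:
        raise Wave2vecError(f"k must be >= 2 (k={k} leaves no held-out data)")
    if k > n:
        raise Wave2vecError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, inst in enumerate(dataset.instances):
        if inst.label is None:
            raise Wave2vecError(f"instance {inst.instance_id!r} is unlabeled")
        by_class.setdefault(inst.label, []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset += len(idx)  # stagger classes so fold sizes stay even
    for fold in folds:
        present = {dataset.instances[i].label for i in fold}
        if present != set(by_class):
            raise StratificationError(
                f"a fold is missing classes {set(by_class) - present}; "
                "use fewer folds or more data per class"
            )
    return folds


def run_cv(
    dataset: LabeledDataset,
    encoder_config: EncoderConfig,
    cbow_config: CBOWConfig,
    k: int = 10,
    seed: int = 0,
    positive_class: str | None = None,
) -> EvalReport:
    """k-fold cross-validated evaluation of the full pipeline.

    Per fold: fit the quantizer on the training deltas, train the CBOW table
    on the training sequences, build one class model per class, then classify
    the held-out fold.  No test-fold information enters any fitting step.
    """
    classes = sorted(dataset.classes)
    if len(classes) < 2:
        raise Wave2vecError("dataset must contain at least 2 classes")
    if positive_class is None:
        positive_class = classes[0]
    if positive_class not in dataset.classes:
        raise Wave2vecError(f"positive_class {positive_class!r} not in dataset")

    signals: list[RawSignal] = dataset.instances
    if encoder_config.target_rate_hz is not None:
        signals = [downsample(s, encoder_config.target_rate_hz) for s in signals]
        encoder_config = EncoderConfig(
            base_n=encoder_config.base_n,
            clip_z=encoder_config.clip_z,
            mode=encoder_config.mode,
            target_rate_hz=None,
        )
    deltas = [delta_encode(s) for s in signals]

    folds = kfold_split(dataset, k=k, seed=seed)
    fold_counts: list[FoldCounts] = []
    for fold_no, test_idx in enumerate(folds):
        test_set = set(test_idx)
        train_idx = [i for i in range(len(signals)) if i not in test_set]
        spec = fit_quantizer(
            [deltas[i] for i in train_idx],
            base_n=encoder_config.base_n,
            clip_z=encoder_config.clip_z,
        )
        train_seqs = [encode_signal(signals[i], spec) for i in train_idx]
        table = train_cbow(train_seqs, cbow_config)
        models = [
            build_class_model(
                [s for s in train_seqs if s.label == label], table, label
            )
            for label in classes
        ]
        fc = FoldCounts()
        for i in test_idx:
            predicted, _ = classify(encode_signal(signals[i], spec), models, table)
            actual = signals[i].label
            if actual == positive_class:
                if predicted == positive_class:
                    fc.tp += 1
                else:
                    fc.fn += 1
            else:
                if predicted == positive_class:
                    fc.fp += 1
                else:
                    fc.tn += 1
        logger.info("fold %d: %s", fold_no, fc)
        fold_counts.append(fc)

    return EvalReport(
        fold_counts=fold_counts,
        positive_class=positive_class,
        config={
            "base_n": encoder_config.base_n,
            "clip_z": encoder_config.clip_z,
            "window_t": cbow_config.window_t,
            "dim_n": cbow_config.dim_n,
            "epochs": cbow_config.epochs,
            "learning_rate": cbow_config.learning_rate,
            "min_frequency": cbow_config.min_frequency,
            "k": k,
            "seed": seed,
        },
    )


def sweep_base_n(
    dataset: LabeledDataset,
    base_n_list: list[int] | None = None,
    encoder_config: EncoderConfig = EncoderConfig(),
    cbow_config: CBOWConfig = CBOWConfig(),
    k: int = 10,
    seed: int = 0,
    positive_class: str | None = None,
) -> list[dict]:
    """Run the cross-validation once per encoding base number.

    Returns one row per base_n with pooled precision/recall/F1/accuracy and
    the realized vocabulary bound — ready for a bar-chart of score vs.
    encoding resolution.
    """
    if base_n_list is None:
        base_n_list = list(DEFAULT_BASE_N_LIST)
    if not base_n_list:
        raise Wave2vecError("base_n_list is empty")
    rows = []
    for base_n in base_n_list:
        cfg = EncoderConfig(
            base_n=base_n,
            clip_z=encoder_config.clip_z,
            mode=encoder_config.mode,
            target_rate_hz=encoder_config.target_rate_hz,
        )
        report = run_cv(
            dataset, cfg, cbow_config, k=k, seed=seed, positive_class=positive_class
        )
        rows.append(
            {
                "base_n": base_n,
                "precision": report.pooled_precision,
                "recall": report.pooled_recall,
                "f1": report.pooled_f1,
                "accuracy": report.pooled_accuracy,
                "alphabet_size": base_n - 1,
            }
        )
        logger.info("sweep base_n=%d: F1=%.3f", base_n, rows[-1]["f1"])
    return rows
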