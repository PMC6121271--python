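"""Seeded generator of two-class signals with planted amplitude-change motifs.

Each instance emulates the structure the classifier assumes: a 1 s,
256-sample, single-channel trace whose successive differences are white
Gaussian noise, with a handful of short class-specific *delta-profile*
motifs added at non-overlapping random positions.  Motifs are defined in
delta space (amplitude-change profiles) rather than amplitude space because
the default encoder is delta-based — the planted pattern survives delta
encoding exactly, which makes ground-truth bookkeeping trivial: with the
noise at zero, the instance's delta series contains each motif profile
verbatim at its drawn position.

The two default class profiles deliberately occupy different parts of the
amplitude-change range (one uses only full-scale rises/drops, the other
mixes full- and half-scale changes).  A mirror-image pair would be invisible
to a bag-of-vectors class model, whose evidence is the per-symbol count
footprint, not the symbol order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoder import QuantizerSpec, quantize
from .errors import PlacementError, Wave2vecError
from .signal_io import write_instance_file, write_labels_manifest
from .types import DeltaSeries, LabeledDataset, RawSignal

__all__ = [
    "Motif",
    "SynthConfig",
    "default_config",
    "generate_instance",
    "generate_dataset",
    "motif_expected_tokens",
    "planted_symbols",
    "write_dataset",
]


@dataclass(frozen=True)
class Motif:
    """A planted pattern: a delta profile, how often it occurs, and its scale.

    The values added to the instance's delta series are
    ``amplitude_scale * profile``, so ``amplitude_scale`` is the motif's peak
    amplitude change in the same units as the noise SD.
    """

    profile: tuple[float, ...]
    occurrences: int = 3
    amplitude_scale: float = 4.0

    def deltas(self) -> np.ndarray:
        return self.amplitude_scale * np.asarray(self.profile, dtype=float)


@dataclass
class SynthConfig:
    n_per_class: int = 100
    length_samples: int = 256
    sampling_rate_hz: float = 256.0
    noise_sd: float = 1.0
    motifs: dict[str, list[Motif]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise Wave2vecError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise Wave2vecError("noise_sd must be non-negative")
        for label, motifs in self.motifs.items():
            for m in motifs:
                if len(m.profile) >= self.length_samples:
                    raise Wave2vecError(
                        f"class {label!r}: motif profile length {len(m.profile)} "
                        f"must be < length_samples {self.length_samples}"
                    )

    @property
    def classes(self) -> list[str]:
        return sorted(self.motifs)


def default_config(
    n_per_class: int = 100,
    noise_sd: float = 1.0,
    amplitude_scale: float | None = None,
    occurrences: tuple[int, int] = (4, 2),
    length_samples: int = 256,
    seed: int = 0,
) -> SynthConfig:
    """Two-class study conditions: planted transients at 4x the noise SD.

    The "alcoholic" class plants a double spike (rise-rise-drop-drop) four
    times per instance; the "control" class plants a single brief spike
    (rise-drop) twice.  All motif deltas are at full amplitude so that,
    after quantization, every planted change lands in the noise-robust
    clipped extreme bins: the classes then differ in their *count* of
    extreme rise/drop symbols, which is exactly the kind of footprint a
    bag-of-wave-vectors class model can discriminate.  (Mid-scale motif
    deltas would be smeared over many narrow bins by the additive noise and
    carry almost no class signal at realistic base numbers; a mirror-image
    motif pair would leave identical footprints and no signal at all.)

    ``amplitude_scale=0`` removes the motifs entirely — both classes then
    share one distribution, the chance-level null condition.
    """
    if amplitude_scale is None:
        amplitude_scale = 4.0 * noise_sd
    occ_a, occ_b = occurrences
    motifs = {
        "alcoholic": [
            Motif(
                profile=(1.0, 1.0, -1.0, -1.0),
                occurrences=occ_a,
                amplitude_scale=amplitude_scale,
            )
        ],
        "control": [
            Motif(
                profile=(1.0, -1.0),
                occurrences=occ_b,
                amplitude_scale=amplitude_scale,
            )
        ],
    }
    return SynthConfig(
        n_per_class=n_per_class,
        length_samples=length_samples,
        noise_sd=noise_sd,
        motifs=motifs,
        seed=seed,
    )


def _place_motifs(
    motifs: list[Motif], n_deltas: int, rng: np.random.Generator
) -> list[tuple[int, Motif]]:
    """Uniform non-overlapping starting positions for every occurrence."""
    placements: list[tuple[int, Motif]] = []
    occupied: list[tuple[int, int]] = []
    for motif in motifs:
        width = len(motif.profile)
        for _ in range(motif.occurrences):
            for _attempt in range(1000):
                start = int(rng.integers(0, n_deltas - width + 1))
                if all(
                    start + width <= lo or start >= hi for lo, hi in occupied
                ):
                    occupied.append((start, start + width))
                    placements.append((start, motif))
                    break
            else:
                raise PlacementError(
                    f"could not place {sum(m.occurrences for m in motifs)} motif "
                    f"occurrences without overlap in {n_deltas} deltas; "
                    "reduce occurrences or motif length"
                )
    return placements


def generate_instance(
    cfg: SynthConfig,
    label: str,
    rng: np.random.Generator,
    instance_id: str | None = None,
) -> tuple[RawSignal, list[dict]]:
    """One synthetic instance plus its ground-truth motif placements.

    The signal is the cumulative sum of white Gaussian deltas
    (SD = noise_sd) with the class's motif delta-profiles added at
    non-overlapping uniform positions.  Deterministic given the generator
    state.
    """
    if label not in cfg.motifs:
        raise Wave2vecError(f"no motif set configured for class {label!r}")
    n_deltas = cfg.length_samples - 1
    deltas = rng.normal(0.0, cfg.noise_sd, size=n_deltas)
    placements = _place_motifs(cfg.motifs[label], n_deltas, rng)
    truth = []
    for start, motif in placements:
        if motif.amplitude_scale != 0.0:
            deltas[start : start + len(motif.profile)] += motif.deltas()
        truth.append(
            {
                "position": start,
                "profile": list(motif.profile),
                "amplitude_scale": motif.amplitude_scale,
            }
        )
    samples = np.concatenate([[0.0], np.cumsum(deltas)])
    signal = RawSignal(
        instance_id=instance_id or f"{label}_{rng.integers(1 << 30)}",
        channel="synthetic",
        samples=samples,
        sampling_rate_hz=cfg.sampling_rate_hz,
        label=label,
    )
    return signal, truth


def generate_dataset(cfg: SynthConfig) -> tuple[LabeledDataset, dict]:
    """n_per_class instances per class plus a ground-truth manifest.

    The manifest records every planted motif's position and profile per
    instance; :func:`motif_expected_tokens` turns a profile into its
    expected symbol subsequence under a fitted quantizer.
    """
    if not cfg.motifs:
        raise Wave2vecError("config defines no classes")
    rng = np.random.default_rng(cfg.seed)
    instances: list[RawSignal] = []
    manifest: dict = {"classes": cfg.classes, "instances": {}}
    for label in cfg.classes:
        for i in range(cfg.n_per_class):
            signal, truth = generate_instance(
                cfg, label, rng, instance_id=f"{label}_{i:04d}"
            )
            instances.append(signal)
            manifest["instances"][signal.instance_id] = truth
    dataset = LabeledDataset(instances=instances, classes=set(cfg.classes))
    return dataset, manifest


def motif_expected_tokens(motif: Motif, spec: QuantizerSpec) -> list[str]:
    """The symbol subsequence a motif encodes to (noise-free) under a spec."""
    seq = quantize(DeltaSeries(deltas=motif.deltas(), source_id="motif"), spec)
    return seq.tokens


def planted_symbols(cfg: SynthConfig, spec: QuantizerSpec) -> dict[str, set[str]]:
    """Per class: the set of symbols its motifs encode to under ``spec``."""
    out: dict[str, set[str]] = {}
    for label, motifs in cfg.motifs.items():
        symbols: set[str] = set()
        for m in motifs:
            symbols.update(motif_expected_tokens(m, spec))
        out[label] = symbols
    return out


def write_dataset(
    dataset: LabeledDataset,
    manifest: dict,
    out_dir: str | Path,
    suffix: str = ".txt",
) -> None:
    """Emit per-instance signal files, a labels TSV, and the truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels: dict[str, str] = {}
    for signal in dataset.instances:
        write_instance_file(signal, out_dir / f"{signal.instance_id}{suffix}")
        labels[signal.instance_id] = signal.label
    write_labels_manifest(labels, out_dir / "labels.tsv")
    with (out_dir / "truth.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
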