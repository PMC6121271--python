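"""Plain data containers shared across the pipeline stages.

A *RawSignal* is one channel's recording of one trial (for EEG: a 1 s,
256-sample evoked-potential trace).  Encoding turns it into a *DeltaSeries*
(successive amplitude changes) and then into a *SymbolSequence* over a finite
alphabet, which is what the embedding and classification stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import Wave2vecError


@dataclass
class RawSignal:
    """One instance: a single channel's real-valued amplitude series."""

    instance_id: str
    channel: str
    samples: np.ndarray  # amplitudes in µV
    sampling_rate_hz: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise Wave2vecError(f"signal {self.instance_id!r}: samples empty")
        if not np.all(np.isfinite(self.samples)):
            raise Wave2vecError(f"signal {self.instance_id!r}: non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise Wave2vecError(
                f"signal {self.instance_id!r}: sampling_rate_hz must be > 0"
            )

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class LabeledDataset:
    """A collection of instances with the set of valid class labels."""

    instances: list[RawSignal]
    classes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [s.instance_id for s in self.instances]
        if len(set(ids)) != len(ids):
            raise Wave2vecError("duplicate instance_ids in dataset")
        for s in self.instances:
            if s.label is not None and s.label not in self.classes:
                raise Wave2vecError(
                    f"instance {s.instance_id!r} labeled {s.label!r}, "
                    f"not in classes {sorted(self.classes)}"
                )

    def __len__(self) -> int:
        return len(self.instances)

    def labels(self) -> list[str | None]:
        return [s.label for s in self.instances]


@dataclass
class DeltaSeries:
    """Amplitude changes between successive samples of one instance."""

    deltas: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)

    def __len__(self) -> int:
        return int(self.deltas.size)


@dataclass
class SymbolSequence:
    """The encoded form of one instance: an ordered list of alphabet tokens."""

    instance_id: str
    tokens: list[str]
    label: str | None = None

    def __len__(self) -> int:
        return len(self.tokens)
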