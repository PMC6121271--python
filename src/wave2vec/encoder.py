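"""Symbolic encoding of real-valued signals.

The default pipeline is *delta encoding* followed by Gaussian quantization:

1. (optionally) decimate the signal to a user-chosen sampling rate;
2. take successive differences — amplitude *changes* have far smaller spread
   than raw amplitudes, so a small alphabet suffices;
3. z-score the changes against the pooled training distribution and map each
   one to a symbol via equal-probability bins of the fitted normal.

Changes beyond ``clip_z`` standard deviations (default ±2) are treated as
noise/sensor artifacts and absorbed into the outermost bins, and the two
near-zero bins either side of the mean are merged into a single center symbol
``U00`` so that sensor jitter is not learned as signal.  The alphabet is
therefore ordered ``D(base_n/2-1) … D01, U00, U01 … U(base_n/2-1)`` — ``D``
symbols for drops, ``U`` for rises — and has ``base_n - 1`` symbols.

A direct-amplitude variant (:func:`quantize_amplitude`) bins raw values into
``base_n`` equal-width levels labeled with base-``base_n`` digits
('0'…'F' for base 16).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .errors import DegenerateDistributionError, Wave2vecError
from .types import DeltaSeries, RawSignal, SymbolSequence

__all__ = [
    "EncoderConfig",
    "QuantizerSpec",
    "downsample",
    "delta_encode",
    "fit_quantizer",
    "quantize",
    "quantize_amplitude",
    "decode",
    "encode_signal",
]


@dataclass(frozen=True)
class EncoderConfig:
    """User-facing encoding parameters.

    ``target_rate_hz=None`` keeps the native sampling rate.  ``mode`` selects
    delta encoding (the default) or the direct-amplitude variant, which also
    needs ``voltage_range``.
    """

    base_n: int = 64
    clip_z: float = 2.0
    mode: str = "delta"
    target_rate_hz: float | None = None
    voltage_range: tuple[float, float] | None = None


def _symbol_width(base_n: int) -> int:
    return max(2, len(str(base_n // 2 - 1)))


def delta_alphabet(base_n: int) -> list[str]:
    """D(base_n/2-1)…D01, U00 (merged center), U01…U(base_n/2-1)."""
    w = _symbol_width(base_n)
    half = base_n // 2 - 1
    down = [f"D{i:0{w}d}" for i in range(half, 0, -1)]
    up = [f"U{i:0{w}d}" for i in range(0, half + 1)]
    return down + up


@dataclass
class QuantizerSpec:
    """A fitted quantization scheme, serializable for bit-exact reruns.

    ``bin_edges`` are on the z-score scale: ``alphabet_size - 1`` strictly
    increasing interior cut points inside ``(-clip_z, clip_z)``; the first and
    last bins extend to ∓∞ so clipped extremes land in the outermost symbols.
    """

    base_n: int
    mu: float
    sigma: float
    clip_z: float
    bin_edges: np.ndarray
    alphabet: list[str]
    mode: str = "delta"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise Wave2vecError("bin_edges must be strictly increasing")
        if len(self.alphabet) != len(set(self.alphabet)):
            raise Wave2vecError("alphabet symbols must be unique")
        if len(self.bin_edges) != len(self.alphabet) - 1:
            raise Wave2vecError(
                f"{len(self.alphabet)} symbols require "
                f"{len(self.alphabet) - 1} edges, got {len(self.bin_edges)}"
            )

    @property
    def alphabet_size(self) -> int:
        return len(self.alphabet)

    def symbol_interval(self, token: str) -> tuple[float, float]:
        """The z-score interval a symbol covers, clip-truncated at ±clip_z."""
        try:
            i = self.alphabet.index(token)
        except ValueError:
            raise Wave2vecError(f"unknown token {token!r}") from None
        lo = -self.clip_z if i == 0 else self.bin_edges[i - 1]
        hi = self.clip_z if i == len(self.alphabet) - 1 else self.bin_edges[i]
        return float(lo), float(hi)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"base_n {self.base_n}\n")
            fh.write(f"mode {self.mode}\n")
            fh.write(f"mu {float(self.mu)!r}\n")
            fh.write(f"sigma {float(self.sigma)!r}\n")
            fh.write(f"clip_z {float(self.clip_z)!r}\n")
            fh.write("alphabet " + " ".join(self.alphabet) + "\n")
            fh.write("bin_edges " + " ".join(repr(float(e)) for e in self.bin_edges) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "QuantizerSpec":
        fields: dict[str, list[str]] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.split()
                if parts:
                    fields[parts[0]] = parts[1:]
        return cls(
            base_n=int(fields["base_n"][0]),
            mu=float(fields["mu"][0]),
            sigma=float(fields["sigma"][0]),
            clip_z=float(fields["clip_z"][0]),
            bin_edges=np.array([float(v) for v in fields["bin_edges"]]),
            alphabet=list(fields["alphabet"]),
            mode=fields["mode"][0],
        )


def downsample(signal: RawSignal, target_rate_hz: float) -> RawSignal:
    """Decimate: keep every r-th sample, r = original rate / target rate."""
    if target_rate_hz > signal.sampling_rate_hz:
        raise Wave2vecError(
            f"target rate {target_rate_hz} exceeds signal rate "
            f"{signal.sampling_rate_hz}"
        )
    ratio = signal.sampling_rate_hz / target_rate_hz
    r = round(ratio)
    if abs(ratio - r) > 1e-9 or r < 1:
        raise Wave2vecError(
            f"rate ratio {signal.sampling_rate_hz}/{target_rate_hz} = {ratio} "
            "is not a positive integer; choose a target rate that divides the "
            "original rate evenly"
        )
    if r == 1:
        return signal
    return RawSignal(
        instance_id=signal.instance_id,
        channel=signal.channel,
        samples=signal.samples[::r].copy(),
        sampling_rate_hz=target_rate_hz,
        label=signal.label,
    )


def delta_encode(signal: RawSignal) -> DeltaSeries:
    """Successive differences: deltas[i] = samples[i+1] - samples[i]."""
    if len(signal) < 2:
        raise Wave2vecError(
            f"signal {signal.instance_id!r} has {len(signal)} sample(s); "
            "delta encoding needs at least 2"
        )
    return DeltaSeries(deltas=np.diff(signal.samples), source_id=signal.instance_id)


def fit_quantizer(
    training_deltas: list[DeltaSeries] | DeltaSeries,
    base_n: int,
    clip_z: float = 2.0,
    mode: str = "delta",
) -> QuantizerSpec:
    """Fit a Gaussian equal-probability quantizer on pooled training deltas.

    The ``base_n - 1`` bins partition the real line; their interior edges are
    the equal-probability quantiles of the fitted Normal(mu, sigma²)
    restricted to ``[mu - clip_z·sigma, mu + clip_z·sigma]``, so each symbol
    covers the same probability mass of the clipped distribution and the
    outermost bins additionally absorb the clipped tails.
    """
    if base_n % 2 != 0 or base_n < 4:
        raise Wave2vecError(f"base_n must be an even integer >= 4, got {base_n}")
    if mode != "delta":
        raise Wave2vecError(f"fit_quantizer supports mode='delta', got {mode!r}")
    if isinstance(training_deltas, DeltaSeries):
        training_deltas = [training_deltas]
    pooled = np.concatenate([d.deltas for d in training_deltas])
    if pooled.size == 0:
        raise Wave2vecError("no training deltas")
    mu = float(np.mean(pooled))
    sigma = float(np.std(pooled))
    if sigma <= 0:
        raise DegenerateDistributionError(
            "pooled training deltas have zero standard deviation; "
            "a constant signal cannot be quantized"
        )
    m = base_n - 1
    lo, hi = norm.cdf(-clip_z), norm.cdf(clip_z)
    # interior equal-probability quantiles of the clip-restricted normal
    probs = lo + (hi - lo) * np.arange(1, m) / m
    edges = norm.ppf(probs)
    return QuantizerSpec(
        base_n=base_n,
        mu=mu,
        sigma=sigma,
        clip_z=clip_z,
        bin_edges=edges,
        alphabet=delta_alphabet(base_n),
        mode="delta",
    )


def quantize(deltas: DeltaSeries, spec: QuantizerSpec) -> SymbolSequence:
    """Map each delta to the symbol of its containing bin (tails clipped)."""
    values = deltas.deltas
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise Wave2vecError(
            f"{deltas.source_id!r}: non-finite delta at index {int(bad[0])}"
        )
    z = (values - spec.mu) / spec.sigma
    idx = np.searchsorted(spec.bin_edges, z, side="right")
    tokens = [spec.alphabet[i] for i in idx]
    return SymbolSequence(instance_id=deltas.source_id, tokens=tokens)


_DIGITS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


def amplitude_alphabet(base_n: int) -> list[str]:
    """Base-``base_n`` digit symbols; decimal index strings beyond base 62."""
    if base_n <= len(_DIGITS):
        return list(_DIGITS[:base_n])
    w = len(str(base_n - 1))
    return [f"{i:0{w}d}" for i in range(base_n)]


def quantize_amplitude(
    signal: RawSignal, base_n: int, voltage_range: tuple[float, float]
) -> SymbolSequence:
    """Direct-amplitude variant: equal-width bins over a fixed voltage range.

    Out-of-range amplitudes clamp to the boundary symbols.
    """
    lo, hi = voltage_range
    if lo >= hi:
        raise Wave2vecError(f"voltage_range: need lo < hi, got [{lo}, {hi}]")
    width = (hi - lo) / base_n
    idx = np.floor((signal.samples - lo) / width).astype(int)
    idx = np.clip(idx, 0, base_n - 1)
    alphabet = amplitude_alphabet(base_n)
    return SymbolSequence(
        instance_id=signal.instance_id,
        tokens=[alphabet[i] for i in idx],
        label=signal.label,
    )


def decode(seq: SymbolSequence, spec: QuantizerSpec) -> DeltaSeries:
    """Map each symbol back to its bin midpoint (clip-truncated at the ends)."""
    mids = []
    for tok in seq.tokens:
        lo, hi = spec.symbol_interval(tok)  # raises on unknown token
        mids.append((lo + hi) / 2.0)
    deltas = spec.mu + spec.sigma * np.array(mids)
    return DeltaSeries(deltas=deltas, source_id=seq.instance_id)


def encode_signal(
    signal: RawSignal, spec: QuantizerSpec, config: EncoderConfig = EncoderConfig()
) -> SymbolSequence:
    """Full per-instance encoding: downsample → delta → quantize.

    The instance label is carried onto the symbol sequence.
    """
    if config.target_rate_hz is not None:
        signal = downsample(signal, config.target_rate_hz)
    seq = quantize(delta_encode(signal), spec)
    seq.label = signal.label
    return seq
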