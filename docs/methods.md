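# Methods

## Model

wave2vec reduces classification of a real-valued single-channel time series
to symbolic sequence classification.  The pipeline has four fitted
components, all trained only on the training portion of any evaluation
split:

**Quantizer.**  Successive differences (deltas) of the training signals are
pooled; their mean μ and standard deviation σ define a z-score
normalization.  The real line is partitioned into `baseN − 1` bins whose
interior edges are the equal-probability quantiles of Normal(μ, σ²)
restricted to [μ − clip·σ, μ + clip·σ] (clip = 2 by default): each symbol
covers the same probability mass of the clipped distribution, and the two
outermost bins extend to ±∞ so that extreme changes — treated as noise or
sensor artifacts — are absorbed into one stage per side rather than
modeled.  The two bins adjacent to zero are merged into a single center
symbol `U00`, covering small changes of either sign, so that sensor jitter
around zero is not learned; the alphabet therefore has `baseN − 1` symbols,
ordered `D(baseN/2−1) … D01, U00, U01 … U(baseN/2−1)`.  Normalization uses
the pooled training statistics, not per-instance statistics, so the fitted
spec transfers unchanged to test data and can be serialized for bit-exact
reruns.  Decoding maps a symbol to the midpoint of its (clip-truncated)
bin, which bounds the reconstruction error of any in-range delta by half
the local bin width.

A direct-amplitude variant quantizes raw values into `baseN` equal-width
bins over a fixed voltage range, with base-`baseN` digit symbols ('0'…'F'
for base 16); it exists for data whose raw levels, not changes, carry the
signal, and plays no role in the default pipeline.

**Wave embedding (CBOW).**  A window of odd length t slides one position at
a time over each encoded sequence; the center symbol is the target and up
to (t−1)/2 symbols per side are the context (truncated at sequence
boundaries, never crossing instance boundaries).  The forward pass averages
the context rows of the V×N input matrix, multiplies by the N×V output
matrix, and applies a full softmax over the V vocabulary symbols;
cross-entropy against the target is minimized by per-window SGD.  Because
V ≤ baseN ≤ 1024, the full softmax is cheap and no hierarchical softmax or
negative sampling is needed.  The input matrix is initialized uniformly in
[−0.5/N, 0.5/N] from the seeded generator, the output matrix at zero, and
the learning rate decays linearly to 10⁻⁴ of its start value across all
updates; a given seed, corpus and configuration reproduce the vector table
bit-for-bit.  A numba-compiled inner loop and a plain numpy loop implement
identical update arithmetic (a test asserts their agreement); the compiled
loop is used when numba is importable.

**Class models and classification.**  A sequence's vector is the sum of its
tokens' wave vectors (out-of-vocabulary tokens are skipped; an all-skipped
sequence is flagged degenerate and refused, never silently classified).  A
class model is the vector sum over all its training sequences.  Cosine
similarity scores a test sequence against every model and the best label
wins, ties broken by model order.  Since cosine ignores magnitude, sum and
mean aggregation — and any positive rescaling of a model — give identical
decisions; tests enforce this direction-only contract.

**Pattern-probability baseline.**  For interpretability and cross-checking,
a count-based classifier scores class c for a sequence as
Σ over distinct patterns of O·S·p(c|pattern) / n, where patterns are the
contiguous n-grams up to a configured length, O is the pattern's occurrence
count in the sequence (so multiplicity is carried by O, not by repeated
summation), S = pattern length (the simplest weight proportional to length,
privileging longer patterns), p(c|pattern) = L/G with L the pattern's
occurrence count within class-c training sequences and G the total count of
all patterns of that length in the training corpus, and n the sequence's
token count.  Ties in the argmax break lexically.

## Evaluation harness

Folds are stratified: each class is shuffled with the seeded generator and
dealt round-robin, with classes staggered so fold sizes stay even; a fold
that cannot contain every class is an error rather than a silent skew.  Per
fold the quantizer, the embedding table and the class models are fitted on
the training portion only.  Precision = tp/(tp+fp), recall = tp/(tp+fn),
F1 = their harmonic mean, computed from pooled fold counts; any 0/0 yields
0 with a warning.  F1 is the primary metric — with imbalanced classes a
majority-class predictor scores deceptively high accuracy — but accuracy is
reported alongside.  The sweep harness repeats the cross-validation over
the 13 encoding base numbers {8, 16, 32, 48, 64, 96, 128, 192, 256, 384,
512, 768, 1024} by default.

## Parameters

| parameter | default | meaning / guidance |
|---|---|---|
| `base_n` | 64 | encoding base number; alphabet size is `base_n − 1`. Small values lose signal detail, large values approach the raw data and dilute token statistics. 64 is a good operating point for 1 s, 256-sample trials |
| `clip_z` | 2.0 | clip radius in pooled SDs; changes beyond it are artifact-like and share the outermost bins |
| `window` | 10 | an odd value is the full window length t; an even value is interpreted as context per side (10 → t = 21) |
| `dim` (N) | 50 | wave-vector dimension |
| `epochs` | 3 | SGD passes; see "short training" below |
| `learning_rate` | 0.05 | initial SGD step, linear decay |
| `min_frequency` | 1 | tokens rarer than this are dropped from the vocabulary and skipped in windows |
| `k` | 10 | cross-validation folds, stratified |
| `noise_sd` | 1.0 | generator: SD of the white Gaussian delta noise |
| `amplitude_scale` | 4·noise_sd | generator: peak motif amplitude change |

### Short training is deliberate

The classifier needs wave vectors whose *relative geometry* reflects
context statistics, not a converged language model.  Two facts motivate the
small epoch default.  First, classification quality on planted-motif data
is already excellent after 2–3 epochs and improves little afterwards — the
class evidence is the per-symbol count footprint, which the class-model
summation extracts from even mildly trained vectors.  Second, per-class
similarity matrices are only comparable if both tables remain anchored to
their common seeded initialization: symbols whose contexts are statistically
indistinguishable (pure background noise) have under-determined vectors,
and long SGD runs let them drift apart between two independently trained
tables, burying the genuinely different (motif) entries of the difference
matrix under drift artifacts.  With 3 epochs the difference matrix is
dominated by symbols whose context distributions truly differ.  Users who
train longer should expect the difference map to grow noisier even as
training loss falls.

## Synthetic data: what it does and does not emulate

The generator emulates the *structure the classifier assumes*: 1 s,
256-sample, single-channel instances whose deltas are white Gaussian noise
(SD `noise_sd`) plus class-specific motif delta-profiles planted at
uniformly drawn non-overlapping positions.  Motifs live in delta space so
they survive delta encoding exactly, which makes ground truth trivially
checkable: at zero noise the delta series contains each profile verbatim.

Default study conditions: 100 instances per class (the recovery experiments
use 300), noise SD 1, motif amplitude 4× the noise SD, and two classes —
one planting a double spike (profile (1, 1, −1, −1), 4 occurrences), the
other a single brief spike (profile (1, −1), 2 occurrences).  Two design
constraints shaped these profiles.  (a) All motif deltas are at full
amplitude: additive noise of 1σ smears any mid-scale delta across dozens of
the narrow interior bins at realistic base numbers, so only the clipped
extreme bins are noise-robust features; classes whose motifs differ only in
mid-scale structure are nearly indistinguishable after encoding.  (b) The
classes must differ in their per-symbol *count* footprint: a bag-of-vectors
class model is order-blind, so a mirror-image motif pair (identical symbol
counts, different order) carries no class signal for it.  With
`amplitude_scale=0` the classes are distributionally identical and pooled
F1 sits at chance — the null control.

Not emulated: realistic EEG spectra (alpha/beta bands), evoked-potential
morphology, inter-subject variability, multi-channel structure, artifacts
other than what the clip absorbs.  Passing the synthetic recovery tests
therefore shows the pipeline correctly extracts planted symbolic structure
at a given signal-to-noise ratio; it does not certify performance on real
EEG, where class differences are subtler and not localized to extreme
amplitude changes.

The expected symbol subsequence of a motif is defined as its noise-free
quantization.  Per planted symbol this is recovered ~93% of the time at
amplitude 4·noise_sd; exact recovery of whole occurrences exceeds 90% once
the amplitude reaches ~6·noise_sd (every planted delta then saturates its
clipped bin despite the noise), which is the condition the fidelity test
uses.

## Numerical choices and degenerate inputs

- Quantile edges are computed on the z-scale with scipy's normal
  inverse-CDF; quantization is a `searchsorted` over them, so monotonicity
  in the delta is structural.
- A zero pooled delta SD (constant signals) is a degenerate-distribution
  error, not a silent division by zero; non-finite deltas name their index.
- Downsampling is strict decimation; non-integer rate ratios are an error
  rather than interpolation, which would manufacture samples.
- Softmax is computed with max-subtraction; a non-finite training loss
  aborts with the epoch and learning rate (divergence error).
- Cosine against a zero vector is an error; sequence vectors that would be
  zero are flagged degenerate upstream.
- Similarity matrices are symmetrized and their diagonal pinned to exactly
  1 to remove float round-off before differencing; the "XOR" difference
  defaults to the elementwise absolute difference (bounded by 2), with a
  thresholded binary XOR available where a hard mask is wanted.
- Tables from different trainings live in different vector spaces; the API
  never compares raw vectors across tables — only their similarity
  matrices, which are basis-free, cross the table boundary.
- Ties: classification by model order, pattern argmax lexically,
  divergent-pair ranking by (row, col) index — all deterministic.

## Known limitations

- The delta/quantile encoder keeps one symbol per sampling interval;
  multi-scale or frequency-domain structure is invisible to it.
- Pattern tokens are unigrams; the embedding sees longer patterns only
  through context windows, and the baseline classifier only up to its
  configured n-gram length.
- The vector-sum class model is order-blind (see the generator discussion);
  discriminative information carried purely by symbol order requires the
  pattern baseline or a sequence model.
- With very small corpora, rare symbols may be absent from a class's
  vocabulary; the visualization workflow restricts matrices to symbols
  present in every compared table.
- Cross-validated runs refit everything per fold, so runtime scales with
  k × corpus size × epochs; the compiled inner loop handles the default
  study sizes in seconds per fold on one CPU.
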