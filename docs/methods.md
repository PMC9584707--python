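# Methods

## The estimator

MM-mDistEn extends distribution entropy (DistEn) along three axes:
*multivariate* (one joint entropy over all channels, via composite delay
vectors), *multiscale* (coarse-graining at factors s = 1…15), and
*modified* (a fuzzy similarity transform with tolerance r and exponent n
applied to the pairwise distances before the histogram is taken).

Classic DistEn histograms the raw inter-vector distances over a
data-driven range, so no tolerance parameter exists. Here each Chebyshev
distance d between composite vectors is first mapped to the fuzzy
membership μ(d) = exp(−(d/r)^n) with r = 0.2 × SD and n = 2, and the
B = 64-bin empirical PDF is taken over the fixed codomain [0, 1] of μ.
This makes r and n genuine parameters of the estimator and has two
useful consequences:

* **Amplitude-scale invariance.** d and r both scale linearly with the
  signal, so d/r — and hence every μ value and the entropy — is exactly
  invariant under positive rescaling. The histogram support being fixed
  at [0, 1] (not data-dependent) preserves this.
* **Reproducibility.** Bin edges never depend on the realized distances.

### Local-baseline removal

Before distances are taken, every channel's m-point delay block loses
its own mean. This is the defining convention of the fuzzy similarity
family the r/n modification comes from, and it matters quantitatively:
without it, at the standard tolerance r = 0.2·SD, the membership
function saturates — nearly all raw inter-vector distances exceed ~2r,
nearly all similarities fall into the first of 64 bins, and the
estimator loses most of its discriminating power (the chaotic and
periodic benchmark series become indistinguishable at the replicate
level). With baseline removal the similarity compares local waveform
shape, recurrences become graded, and the three benchmark dynamics
separate with zero overlap across seeds. `EntropyConfig(baseline="none")`
restores the raw-vector variant for comparison.

### Why the sinusoid scores *highest*

With the fuzzy transform, entropy measures the *spread of the
similarity distribution*, not raw unpredictability. A periodic signal
revisits its states at every lag, producing similarities across the
whole (0, 1] range → a broad PDF → high entropy. White noise almost
never recurs within tolerance: similarities concentrate near 0 → a
nearly degenerate PDF → low entropy. Chaos, with its fractal
recurrence structure, sits in between. The resulting strict ordering
(sinusoid > chaotic > Gaussian noise) is the discrimination property
the estimator is validated on; note its direction is the reverse of
what holds for sample-entropy-style counting statistics.

## Parameters

| parameter | default | role |
|---|---|---|
| m | 3 | embedding dimension; uniform across channels |
| τ | 1 | embedding delay (samples of the coarse-grained series) |
| r | 0.2 × SD | fuzzy tolerance (breadth); SD is the pooled population SD of the coarse-grained matrix, recomputed at every scale |
| n | 2 | fuzzy exponent (steepness) |
| B | 64 | histogram bins |
| s | 1…15 | coarse-graining factors; requires ⌊N/s⌋ − (m−1)τ ≥ 2 |

Per-channel embedding parameters (m_c, τ_c) are representable in the
general formulation but deliberately not supported: uniform values are
the only configuration in practical use, and per-channel values would
make channel-permutation invariance configuration-dependent.
`sd_mode="per_channel"` (mean of per-channel SDs) is available as an
alternative tolerance convention; the pooled default treats the
multichannel recording as one data cloud.

## Numerical choices

* Coarse-grain windows follow the 1-based convention (samples
  (j−1)s+1 … js); the trailing N mod s samples are discarded.
* Histogram boundaries: interior bin edges assign upward; 1.0 (an exact
  self-similarity, impossible for i ≠ j pairs unless two vectors
  coincide) falls in the last bin.
* 0·log 0 := 0 for empty bins; logarithms are base 2 throughout, and
  the 1/log₂B prefactor bounds the entropy in [0, 1].
* Zero-variance input makes r = 0; the estimator raises
  `DegenerateSignalError` rather than returning a value.
* Chebyshev distance is the default metric (the DistEn convention);
  Euclidean is available via config.

## Synthetic data: what it emulates and what it does not

The benchmark generators produce the classic validation triplet —
Gaussian white noise, the fully developed logistic map
x_{t+1} = 4x_t(1−x_t) (100-iteration burn-in; initial conditions whose
orbit collapses onto a fixed point are redrawn, or rejected when given
explicitly), and a sinusoid — at 400 samples each, plus 1/f pink noise
as a fourth kind.

The two-class labeled dataset emulates the *shape* of a consumer-EEG
emotion experiment: 28 subjects × 20 trials, 14 channels at 128 Hz,
512 samples (4 s) per trial, with continuous 1–9 ratings straddling the
4.5 binarization threshold. Channels are generated as coherent mixtures
of 3 shared sources plus 5% independent sensor noise, mimicking volume
conduction. This inter-channel correlation is not cosmetic: a joint
Chebyshev distance over 14 *independent* channels essentially never
registers a recurrence (the independent noise alone pushes every
pairwise max-coordinate distance past the fuzzy cutoff), and the
estimator degenerates to 0 for any class. Realistic scalp recordings
are strongly correlated across electrodes, and the estimator's joint
multichannel construction implicitly assumes that.

The class contrast is statistical, not neural: class 0 (low rating)
sources are narrowband theta/alpha oscillations, class 1 (high rating)
sources are broadband noise. Passing the end-to-end test therefore
shows that the pipeline recovers a *large, constructed* irregularity
difference through the full feature → classifier → CV chain — it says
nothing about effect sizes in real emotion EEG, where reported
accuracies depend on dataset, preprocessing and subject.

Problem sizes in the shipped tests and acceptance script (50 oracle
signals at N ≤ 100, 20 replicates of the 400-sample benchmarks, one
28-subject dataset) were chosen as the smallest sizes at which the
checked properties are stable across seeds.

## Classifier

The network is a fully connected [64, 32] ReLU stack with a sigmoid
output unit, trained with RMSprop (learning rate 10⁻³, decay 0.9,
ε = 10⁻⁸) on binary cross-entropy, mini-batches of 16, at most 300
epochs with early stopping on a training-loss plateau (patience 20,
tolerance 10⁻⁶). Weights use He initialization from a seeded generator,
so training is bit-reproducible. The layer widths, epoch/batch numbers
and stopping rule are free design choices exposed in `NetworkSpec`; the
activation/optimizer/loss triple is the method's fixed recipe.

Evaluation is stratified 10-fold cross-validation, one network per
subject. Per-feature standardization is fit on each training split only
(no leakage) and travels with the model. Metrics are computed from the
per-fold confusion counts; a degenerate denominator (e.g. a fold with
no positive predictions) yields a 0% sentinel with a warning rather
than NaN, so batch reports always complete. Ratings exactly at 4.5 are
assigned to "low" (the binarization defines only strictly-above as
high; the tie rule is documented here and in the code).

## Known limitations

* The joint-channel entropy is informative only when channels are
  substantially correlated (see above); for nearly independent channels
  use channel-group features (`extract_features(groups=...)`) on small
  subsets instead.
* Runtime and memory are quadratic in the number of embedding vectors
  (V(V−1)/2 distances); recordings much longer than ~10⁴ samples per
  scale should be windowed upstream.
* Loaders accept the generic channel-matrix CSV format only; dataset-
  specific ingestion (proprietary EEG containers, artifact removal,
  filtering) is out of scope and assumed done upstream.
* No per-band spectral decomposition: entropy is computed on the
  broadband signal.
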