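# Methods

This note documents the models, conventions and design choices behind
`asfemg`, in the spirit of the methods documentation of mature scientific
Python packages: what is computed, under which assumptions, and what the
synthetic experiments do and do not demonstrate.

## Signal model and calibration

Recordings are four-channel surface EMG (FCR, FCU, APB, EDC) sampled at
1000 Hz with 16-bit resolution. ADC codes map to millivolts through the
affine transfer function

    EMG_mV = ((ADC / 2^n) − 1/2) · VCC / G · 1000,

with operating voltage VCC = 3 V, amplifier gain G = 1000 and n = 16.
The mid-scale code 2^(n−1) maps to exactly 0 mV; codes 0 and 2^n map to
the ±1.5 mV device endpoints. The full-scale code 2^n is accepted
inclusively so the endpoints are representable; the inverse mapping used
when writing synthetic data rounds to the nearest code, making
quantisation error at most one LSB (45.8 nV).

## Preprocessing

* **Band-pass**: Butterworth, 20–300 Hz, 4th-order analog prototype
  applied to the band (8 poles total), run forward–backward
  (`sosfiltfilt`) for zero phase. Zero phase matters because burst peak
  times drive segmentation; a causal filter would bias them by the group
  delay. The passband follows standard surface-EMG practice: below 20 Hz
  lies motion artefact, above 300 Hz mostly noise at this electrode
  geometry.
* **Hampel**: sample *i* is replaced by the median of the 100
  neighbouring samples (50 each side, centre excluded) when it deviates
  from the neighbour mean by more than 2 neighbour standard deviations.
  The mean/SD form (rather than the classical median/MAD) is the
  documented convention of this pipeline; the centre sample is excluded
  so an isolated spike cannot mask itself, and the replacement value is
  the neighbour median. Edge samples use truncated neighbourhoods. The
  filter is idempotent on outlier-free signals.
* **RMS envelope**: centred moving RMS, default 50 ms window — shorter
  than a burst (0.5 s), longer than one carrier period — with reflective
  edge padding; output length equals input length.
* **Normalization**: per-channel z-score (default) or unit-max, applied
  to the cleaned recording before segments are cut. Degenerate (constant)
  channels raise an error naming the channel.

Features are computed on the filtered, Hampel-cleaned, normalized signal;
the RMS envelope is used only for peak detection. Spectral, wavelet and
fractal features are not meaningful on a rectified envelope, which is why
the filtered-signal path is the default (the envelope path can be
selected by passing the envelope recording to the extractor).

## Segmentation

Detection operates on the moving-average-smoothed (default 0.1 s) sum of
the four channel envelopes — one detection function for all channels.
The candidate set is pruned in four steps:

1. local maxima closer than 0.1 s merge, keeping the larger;
2. candidates below a height floor (baseline + 25% of the envelope's
   dynamic range) are discarded, and candidates sharing one contiguous
   above-floor region merge to the region's tallest — this pair of rules
   is the automated counterpart of the visual inspection step that
   rejects idle-noise candidates and plateau ripple;
3. a scale-free prominence gate discards candidates whose prominence is
   below the 0.25 quantile of neighbouring peak-height differences;
4. within each repetition block (blocks are delimited by idle gaps longer
   than 2 s) the first and last candidates are dropped until at most 8
   remain, mirroring the practice of discarding the first and last
   repetitions of a guided 10-repetition set as unreliable.

Each retained peak yields a segment spanning 30 ms before to 60 ms after
the peak — 90 samples at 1000 Hz — on all four channels. The alternative
reading of the window rule (30/60 ms windows on each side) is not used.
Rest segments are cut with the same geometry at the centres of idle
intervals supplied explicitly. `misdetection_report` counts ground-truth
bursts with no detection within 0.1 s; on dropout-free synthetic data the
detector finds all retained (2nd–9th) bursts.

## Feature sets

All formulas use the 1-based index n = 1..N over the 90-sample window;
the 0-based storage mapping is fixed in one place. Conventions that were
genuinely open and are now fixed:

* **TM4/TM5**: absolute value of the m-th raw temporal moment.
* **LCARD**: log(1 + number of amplitude equivalence classes) with
  merge threshold 0.001 (classes found by sorting and splitting at gaps
  above the threshold).
* **HHT**: in-package EMD (cubic-spline envelopes anchored at the window
  endpoints, Cauchy-type stopping at SD < 0.2, at most 64 siftings);
  the scalar is the energy-weighted mean instantaneous frequency of
  IMF-1, a standard summary in muscle-fatigue analysis. Windows without
  extrema return 0 with a log notice.
* **Wavelet energy (MEWP/MEWT)**: wavelet-packet decomposition to level
  J = floor(log2 N) − 2 (level 4 at N = 90), zero-extension boundaries,
  per-node energy (1/K)ΣW²; MEWP reduces nodes by the median, MEWT by
  the mean. Wavelets: Db8 for the non-paretic set, Db4 for the paretic
  set and standalone ASF-4. Zero extension keeps the decomposition
  identical to a plain convolution–decimation cascade, which the test
  suite exploits as an independent oracle.
* **KT**: the bias-corrected sample excess kurtosis G2 (the printed
  source formula for this feature family omits the s⁴ normalisation,
  without which the statistic is not dimensionless).
* **WL**: waveform length restricted to steps exceeding 5% of the
  largest step — the only role a threshold can play in a length sum.
* **MFL / LRMSV on all-zero windows**: log(0) is replaced by a −10⁶
  sentinel with a log notice, keeping vectors of silent rest segments
  finite.
* **Spectra**: one-sided FFT of the demeaned, rectangular-windowed
  segment, no zero padding, DC bin dropped. PSD scaling satisfies
  Parseval (ΣPSD = mean-square power), so SMD equals half the signal
  power. MMDF/SMD are half-sums as their defining formulas state —
  despite names suggesting median frequencies. MASP splits the one-sided
  |FFT| into 5 equal contiguous bands, each summed and divided by N.
* **AR3/LPC3**: Yule–Walker via Levinson–Durbin on the demeaned window
  (a0 = window mean) and autocorrelation-method linear prediction on the
  raw window (b0 = gain); both 4-value blocks as defined.
* **STFT**: Hamming window of length N/4, 50% overlap, mean spectrogram
  magnitude. **STW**: frequency-domain discrete Stockwell transform,
  mean magnitude over [0, fs/2]; the zero-frequency voice is the window
  mean per the standard convention.
* **HFD**: Higuchi curve-length slope over k = 1..8, clamped to [1, 2]
  with a log notice (constant windows return 1 by convention).
* **FER-4**: per-channel mean absolute value over the EDC channel's,
  normalised by the largest ratio — the only cross-channel component.

Registry counts are asserted at import: ASF-4 has 4 named components
producing 5 scalars per channel (TM4-5 is a twofold component); the
non-paretic and paretic sets have exactly 14 and 24 named components.
With AR3/LPC3 (4 values each) and MASP (5 values), the per-segment
vector lengths are 20, 56 (13×4 + FER-4) and 136 (34×4).

## Separation, reduction, classification

* **RES**: centroid root-mean-square distance divided by the pooled
  per-dimension SD averaged in quadrature; computed on whole vectors by
  default, per feature on request. Rotation-invariant and monotone in
  centroid separation.
* **PCA**: matrices are standardized per training fold; component signs
  are fixed by making each component's largest loading positive; sweeps
  refit standardizer and PCA inside every training fold and select the
  best count by mean macro-F1, smallest on ties (cheaper vectors are
  preferred for eventual real-time use).
* **Classifiers**: SVM with RBF kernel, C = 1, `gamma="scale"` (the
  standard default in the sEMG literature; kernel configurable); LDA in
  closed form; k-NN with k = 5 (odd, avoiding vote ties) and Euclidean
  distance. No class reweighting by default.
* **Cross-validation**: a stated "10-fold, 16 training / 3 testing of 19
  subjects" protocol is internally inconsistent (19 subjects do not make
  10 subject-level folds of 3); the implementation adopts the stricter
  reading — repeated subject-grouped hold-out with 3 random held-out
  subjects per partition, folds × iterations partitions from one seed.
  Benchmarks in this package use 10 × 10 = 100 partitions; the full-scale
  protocol (10 × 100) is a parameter change. Accuracy is micro
  (trace/total), model F1 the macro mean of per-class 2TP/(2TP+FP+FN);
  classes never occurring in a partition are skipped with a notice.
  Paired two-sided t-tests compare configurations over matched
  gesture-combination means; a 1-combination group (GL7) is reported as
  not testable.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not muscle physiology. Each gesture repetition is band-limited Gaussian
noise (carrier bands within 20–300 Hz, mildly gesture-specific, emulating
force- and muscle-dependent spectral shifts) under a Tukey (α = 0.9)
envelope of 0.5 s, scaled per channel by the gesture's activation
pattern; repetitions are 1.5 s apart within a block, blocks 3 s apart,
so the 2 s block-gap rule and the 0.1 s peak spacing are unambiguous.
Dominant-channel bursts exceed the rest-level envelope by well over 6 dB
on the non-paretic side. Background activity is stationary in-band noise
at a burst-to-background SNR drawn per subject.

Paretic-side degradation: amplitude scaling (paresis), linear
inter-channel crosstalk (each channel receives a fraction of the mean of
the others — the simplest mixing that reproduces flexor-gesture
confusability), a lower SNR, and failed bursts dropped with a per-subject
probability. Per-subject channel gains and activation tilts are drawn
from a side-independent stream (both limbs share the subject's
physiology); all other draws are side-specific. Everything derives
deterministically from one seed.

Cohort profile distributions (uniform; chosen once as plausible for an
early post-stroke cohort): paretic amplitude scale 0.4–0.8, crosstalk
0.05–0.30, non-paretic SNR 18–24 dB, paretic SNR 4–8 dB lower, failed
bursts 5–15% (bracketing the 12–15% affected-side misdetection rates
reported in practice). Samples are clipped to the ±1.5 mV device range
before quantisation.

**What passing tests show — and don't.** The synthetic cohort's
activation patterns are cleanly separable, so grouped-CV accuracies near
99% exceed what clinical recordings yield (high-80s/mid-90s); the cohort
demonstrates that the pipeline recovers known structure end to end, that
no information leaks across subject boundaries (label permutation drives
accuracy to chance), and that the degradation model reduces but does not
destroy separability. It does not demonstrate clinical performance:
electrode-placement variability, spasticity-dependent co-activation,
fatigue and true inter-subject physiological diversity are not modelled.

## Problem sizes

Default benchmark sizes were chosen to keep a full desk run in minutes:
19 subjects × 2 sides × 10 repetitions of 6 gestures, 100 CV partitions
per gesture model, all twenty 4-gesture models (~2–3 minutes total on one
CPU). The exhaustive 1–50 component sweep over every gesture-model size
is supported by the API but not run by default; examples use reduced
component grids.

## Known limitations

* The EMD implementation anchors spline envelopes at window endpoints
  rather than mirroring extrema; on 90-sample windows this damps end
  swings but slightly biases IMF-1 near the edges.
* The Hampel rule with mean/SD statistics fires more readily on heavy-
  tailed bursts than the classical median/MAD form; both the window and
  the deviation multiplier are configurable.
* `misdetection_report` matches by nearest peak within 0.1 s and does
  not penalise spurious extra detections; pair it with the per-block
  count cap when auditing a detector.
* Segment-level (rather than subject-level) cross-validation can be
  obtained by passing per-segment identifiers as the `groups` argument;
  it is knowingly optimistic and suitable only for sensitivity analysis.
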