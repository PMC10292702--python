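# Methods

This note documents the models, parameter choices and known limitations of
the package, in the order the pipeline runs.

## Synthetic SEMG surrogate

The clean SEMG surrogate is a zero-mean Gaussian process, band-limited by a
4th-order zero-phase Butterworth band-pass and amplitude-modulated so the
windowed RMS ramps linearly between `rms_start` and `rms_end` over the
recording. The synthesis band is 20–450 Hz at fs = 1,000 Hz: the upper edge
sits 50 Hz below the 500 Hz acquisition-band edge so the filter has a guard
band below Nyquist and no aliased edge effects. A drifting spectral centre
(`mpf_start → mpf_end`) is realised by filtering the same white-noise draw
through per-block band-passes (1 s blocks, ±100 Hz around the target
centre, clipped to the synthesis band) and cross-fading with a 50 %-overlap
Hann window; for a constant centre a single static filter is used.

Contamination is additive and separately controllable: white Gaussian noise
(σ in mV), 50 Hz power-line interference, and 0.5 Hz sinusoidal baseline
wander, with phases drawn from the seed. The clean reference is returned
alongside, so SNR/RMSE can be scored against known truth.

What the surrogate does **not** emulate: motor-unit action potentials and
recruitment, amplitude spikiness (real SEMG is leptokurtic), nonstationary
bursts, or electrode artifacts. Its Gaussianity matters downstream (see the
benchmark regime below): passing tests show the pipeline's numerics and
contracts are right, not that classification or denoising performance
transfers quantitatively to recordings.

Labeled window sets draw `n_per_class` fixed-length windows per class from
a non-fatigued and a fatigued profile (defaults 0.5 vs 2.0 mV RMS, white
noise σ = 0.1 mV) and shuffle them deterministically. The default study
size is 1,000 windows per class, i.e. 2,000 total, so a 7:3 stratified
split yields 1,400 training and 600 evaluation windows.

## Wavelet denoising

Decomposition uses db4 with 4 levels and symmetric signal extension
(configurable); reconstruction truncates to the original length. The noise
scale is the median absolute finest-level detail coefficient divided by
0.6745, and one global λ = σ·√(2 ln N) (N = signal length, natural log) is
applied to every detail level; the approximation is never touched. Three
shrinkage rules are provided. The improved rule's shape parameter k
defaults to 2; larger k moves it toward hard thresholding, and it is
continuous at |w| = λ where both branches give sign(w)·λ/(k+1). Note the
soft/hard "sandwich" |soft| ≤ |improved| ≤ |hard| holds for |w| ≥ λ; below
the threshold the improved rule deliberately keeps a small shrunken value
(|W| ≤ |w|, vanishing as k → ∞) instead of zeroing, which is what
distinguishes it from both classical rules.

**Benchmark regime.** The three-way benchmark (20 replicates, 5 s signals,
≈1 mV RMS) contaminates the surrogate with white σ = 2.0 mV plus 0.3 mV
power line and 0.3 mV drift, i.e. input SNR ≈ −6 dB. The heavy-noise
operating point is deliberate: because the surrogate is a Gaussian process,
its wavelet representation is not sparse, so the universal threshold —
whose σ estimate assumes noise-dominated finest details — only improves SNR
when noise actually dominates. In that regime denoising gains ≈5 dB and the
mode ordering is stable across seeds (improved best, soft second, hard
worst in mean SNR; reversed in RMSE). At low noise the same pipeline
*degrades* a Gaussian surrogate, which a user should expect when applying
universal-threshold denoising to signals that are themselves noise-like.
The 0.5 Hz baseline wander falls into the untouched approximation band
(0–31 Hz at 4 levels) and is borne equally by all modes.

## Fatigue features

IEMG integrates the rectified signal |x(t)| by the trapezoidal rule at 1/fs
spacing — without rectification the integral of a zero-mean signal carries
no recruitment information. RMS uses trapezoidal integration of x² over the
window span. MPF is the spectral centroid of a Welch estimate (Hann window,
a single segment equal to the window, so for 1 s windows the bin width is
1 Hz) restricted to the analysis band, which defaults to the 20–500 Hz
acquisition band. Windows default to 1 s with 50 % overlap; a trailing
partial window is dropped. IEMG and RMS scale linearly with the signal,
MPF is scale-invariant; these identities are tested to 1e-9.

## Fatigue-state classification

The reference classifier is a single recurrent LSTM layer of 100 units over
the window sequence, a ReLU stage on the final hidden state, and a sigmoid
output, trained with Adam (batch 70, learning rate 10⁻³), binary
cross-entropy, gradient-norm clipping at 5, and early stopping (patience 10
on a 10 % validation carve-out of the training split, best weights
restored; max 200 epochs). Both the LSTM and the 1-D CNN baseline are
implemented directly in numpy with analytically verified gradients; all
initialisation and data ordering flows from one integer seed, so
same-machine reruns are bit-identical (cross-platform bit-identity is not
promised).

**Input representation.** Windows are downsampled to 200 time steps by
*block RMS* rather than block averaging: block means of a zero-mean
band-limited process are near zero and erase the amplitude envelope that
carries the fatigue label, whereas block RMS preserves it. With block-mean
input both networks sat at chance level for most seeds at the stated
learning rates; with the envelope input they converge within a few epochs.
The CNN (two strided conv+ReLU stages, 8 and 16 channels, global average
pooling) uses a 10⁻² learning rate — with its default two gradient steps
per epoch the 10⁻³ rate used for the LSTM moves its few parameters too
little within a reduced-epoch budget.

Baselines: RBF-kernel SVM and a one-hidden-layer (32-unit) back-propagation
network on the standardized (IEMG, RMS, MPF) triple per window. Degenerate
training sets (constant windows or constant features) yield a flagged
majority-class predictor rather than a failed fit. Evaluation computes
accuracy, sensitivity, specificity and precision from the stored confusion
matrix; single-class evaluation sets are rejected because sensitivity or
specificity would be undefined.

Tests and the acceptance script run the networks at reduced problem sizes —
200 + 200 windows, 12–25 epochs — chosen so the whole suite stays desk
scale; the separable-class task converges well inside that budget.

## Ultrasound phantom

Frames are piecewise-constant depth profiles (four echogenicity bands
delimited by the surface, surface/deep and bottom boundary depths)
multiplied by a frozen multiplicative speckle field, quantized to 8 bits.
The speckle field is Rayleigh-distributed, rescaled to unit mean and
blended as 1 + scale·(R − 1), so layer means are preserved (unit-mean
speckle) and `speckle_scale = 0` gives a noiseless phantom;
`speckle_grain_px` sets the speckle cell size by block replication, giving
a controllable texture coarseness. The whole tissue — profile and speckle
alike — shifts axially by `frame_displacement_mm` per frame (rounded to
integer rows per frame), so block-matching sees a consistent moving
texture, and ground-truth boundary depths are attached per frame.
Boundaries that would leave the image during the sequence are rejected at
construction. Not emulated: point-spread blur, depth attenuation, shadowing
and reverberation, out-of-plane motion, sub-pixel displacement.

## Tracking, thickness, texture

Tracking matches the frame-0 template (no template update, so no drift
accumulation) by exhaustive integer-pixel normalized cross-correlation
search within ±`search_margin` of the previous position. Correlation ties
are broken by smallest displacement, then lexicographic (row, col). A
constant template is rejected (zero variance); if the search window is
clipped by the frame border and the winning position touches that border,
the trajectory is truncated and flagged. Thickness converts boundary rows
to mm via the pixel spacing (surface = deep − surface rows, deep = bottom −
deep rows, total = sum). The mean response amplitude of an ROI is its mean
pixel magnitude rescaled from the 8-bit range to [0, 1].

GLCM texture uses uniform quantization of the full 8-bit range into L = 32
levels, unit offsets in the four standard directions (0°, 45°, 90°, 135°),
accumulated and symmetrized, then normalized to sum 1; ASM, contrast and
HOM follow the standard formulas. With a normalized matrix, ASM and HOM lie
in (0, 1] and contrast is non-negative by construction (zero exactly when
the matrix is diagonal) — negative contrast values are impossible under
this definition. The implementation is verified exactly against a
brute-force pair-enumeration oracle and against scikit-image for the
standard directions.

## Group comparison

Endpoint comparisons between two arms use Welch's unequal-variance
two-sided t-test with per-endpoint significance at α = 0.05; no
multiplicity correction is applied by default (an optional Holm step-down
is provided). Two distinct constant groups are reported as a certain
difference; two identical constant groups are rejected as degenerate. The
test's null rejection rate is verified to sit near α by simulation.

## Numerical and degenerate-input choices

- SNR of a perfect estimate is reported as +inf (sentinel), not an error.
- λ = 0 thresholding reconstructs the input to 1e-8 relative error (the
  DWT round trip is exact to numerical precision).
- Zero in-band power makes MPF undefined and raises, as does a constant
  patch in normalized cross-correlation.
- `universal_threshold` accepts non-integer N (used by closed-form tests).
- Quantization bins the representable range, not the observed range, so
  texture features are comparable across frames and sequences.

## Limitations

Everything here is validated on surrogates whose limitations are listed
above; absolute classifier accuracies, SNR gains and texture values will
differ on clinical recordings. The tracker is integer-pixel and purely
axial-translation in its phantom validation; the thickness measurement
assumes boundary rows are given (from ground truth or user-marked ROIs) —
no automatic fascia segmentation is attempted.
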