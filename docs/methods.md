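# Methods

## Signal model of the synthetic generator

A trial of stimulus frequency `f ∈ {8, 11, 14}` Hz on channel `c` is

    x_c(t) = Σ_h a_{c,h} · g_s · (h+1)^{−τ_s} · sin(2π (h+1) f t + φ_{s,h}) + n_c(t)

with three harmonic components (`h = 0, 1, 2`), base amplitudes decaying as
`a_{c,h} = A_c / (h+1)` — SSVEP energy concentrates at the fundamental and
falls off over harmonics — and background noise `n_c` drawn as Gaussian
white noise shaped to `1/f^α` with `α = 1` (pink), the simplest surrogate
for the low-frequency-dominated EEG background, with `noise_sd = 1 µV`.
Trials last 5 s at 250 Hz (1250 samples), six blocks per subject by
default, every (subject, block, frequency) combination exactly once.

Subject individuality enters through three quantities drawn once per
subject from the seeded stream: the harmonic phases `φ_{s,h}` (uniform),
a response gain `g_s` (lognormal, sd 0.2 in log), and a harmonic-decay
tilt `τ_s` (uniform ±0.3) that reshapes the relative harmonic amplitudes.
The phases alone would not differentiate subjects in this pipeline —
rectangular 1 s frames at integer frequencies make the magnitude spectrum
phase-invariant — so the gain and tilt carry the subject-specific spectral
structure that makes generalization to unseen subjects genuinely harder.

### Channel profiles and SNR calibration

The default nine-channel set reproduces the occipital-to-temporal quality
gradient of scalp SSVEP: fundamental amplitudes are calibrated (by
bisection against the realized narrowband SNR of simulated 1 s segments,
K = 5, Δf = 1 Hz) so that Oz sits at 7.54 dB and T7/T8 at 0.35 dB — the
set-points used throughout — with PO7/PO8, P7/P8 and TP7/TP8 linearly
interpolated in dB between those anchors (5.74, 3.95, 2.15 dB). The
`calibrate_snr` routine scales the whole harmonic stack proportionally,
preserving the decay ratios while steering the fundamental's SNR; common
random numbers across bisection steps make the calibration deterministic.

What the generator does **not** emulate: volume conduction and channel
correlation (channels get independent noise), eye/muscle artifacts,
non-stationarity within a session, inter-block drift, and the 40-frequency
stimulus grid of full speller datasets. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that its comparative findings
hold under a controlled SNR contrast — not that the absolute accuracies
transfer to any particular real recording.

## Preprocessing

The nominal 5–125 Hz passband is realized as a 4th-order Butterworth 5 Hz
high-pass applied forward-backward (zero phase): at 250 Hz sampling the
upper edge coincides with Nyquist, so only the lower edge is meaningful.
The transition band of this filter is gentle (−6 dB at 5 Hz after the two
passes, −24 dB by 2.5 Hz); content at 8 Hz and above is preserved within
1 dB, which is what the stimulus bands require. Frames are non-overlapping,
rectangular and start-anchored: at 1 Hz resolution the integer stimulus
frequencies are exactly bin-centered, so no taper is needed. A 250-point
FFT yields 126 non-negative-frequency bins; the DC bin is dropped and bins
1–125 Hz form the image rows. Images are scaled to [0, 1] by their own
maximum before classification, removing inter-channel amplitude information
the classifier should not exploit (disable with `preprocess(...,
normalize=False)`).

A trial's shorter-than-5 s windows are taken from the start of the valid
segment (one window per trial); sliding-window augmentation is deliberately
not performed.

## Classifier

The CNN is implemented directly on numpy: im2col convolutions with "same"
padding, non-overlapping max pooling, inverted dropout, manual
backpropagation, and Adam with the standard bias correction. Pooling
windows are 2×2 while the time axis has ≥2 columns and 2×1 after it
collapses, so all widths 1–5 produce a 31×1×16 feature map (496 features)
ahead of the 256-unit dense layer; total 129 379 parameters. He-normal
initialization; float32 arithmetic. The pooling geometry and padding are
recorded in `ArchitectureSpec` as this package's choices — they are not
dictated by the reference architecture, which leaves them open.

Training runs exactly `max_epochs` epochs (default 100) with no early
stopping; per-epoch mean minibatch loss and, when a validation set is
passed, evaluation-mode validation loss/accuracy are recorded. All
randomness (initialization, shuffling, dropout) flows from one seeded
generator, so fixed seed + fixed data order reproduces the loss history
bit-for-bit. Ties in the output argmax resolve to the lowest class index;
classes are ordered by ascending stimulus frequency.

## Binaural fusion

Per output node, ordinary least squares with intercept maps the two ear
softmax readings to the occipital one; the three regressions are
independent, mirroring the per-node formulation. `numpy.linalg.lstsq`
solves the normal equations via the pseudoinverse, so rank-deficient
designs (e.g. identical ear channels) return the finite minimum-norm
solution rather than failing. Re-estimated scores are used argmax-only and
are deliberately not clipped or renormalized. The fit uses the pooled
validation partition of the running scheme; no regularization by default
(the fit is 3 unknowns per node). Fusion requires ≥4 paired samples; the
harness guarantees a per-class minimum in its validation partitions.

## Evaluation schemes

"90 % training / 10 % testing with 5-fold cross-validation" is internally
inconsistent (five disjoint folds would imply 20 % tests), so the
subject-dependent scheme is realized as five independent class-stratified
90/10 resamples. Splits are made at the **trial** level: all nine channel
views of a trial stay on one side, which keeps the paired Oz/T7/T8 softmax
triples intact for the fusion fit and prevents a trial's other channels
from leaking into training. Within each fold, 10 % of the training trials
(at least two per class) are held out as the validation partition that
fits the fusion and monitors training.

The subject-independent scheme shuffles subjects into equal groups
(deterministically under the seed) and tests each group against a model
trained on the others; disjointness of train and test subject sets is
asserted on every fold. avT7T8 is computed per subject as the arithmetic
mean of that subject's T7-only and T8-only accuracies; the significance
column is a two-sided paired t-test of regressed vs avT7T8 per-subject
accuracies (a sign-flip permutation test is available via
`paired_comparison(..., method="permutation")` — the t-test is an
assumption, the underlying study only reports p-values).

ITR uses `T = window + 0.55 s` (gaze-shift convention). Note the bracketed
ITR term is a Kullback–Leibler divergence: it is zero at chance and
positive elsewhere, never negative; below-chance accuracies are flagged
with a warning because the positive rate then reflects systematic
confusions rather than usable throughput.

## CCA baseline

References are unit sine/cosine pairs at the fundamental and up to
`n_harmonics` (default 3) multiples; canonical correlations come from the
QR+SVD route (economic QR of the centered blocks, singular values of
`Qxᵀ Qy`), which reduces to the absolute Pearson correlation in the
single-channel, single-column case. The detector picks the frequency with
the largest leading correlation, ties to the lowest frequency.

## Problem sizes

The packaged experiments run at a reduced scale chosen to exercise every
code path with meaningful statistics: 10 subjects × 2 blocks × 3
frequencies (60 trials, 540 nine-channel spectrograms) for the scheme
comparisons, 5 seeds for directional claims about accuracy orderings, 10
seeds for the CNN-vs-CCA comparison, and 200 images for the separability
check. At this scale a full subject-dependent evaluation (five folds × 100
epochs) completes in about a minute on one core. The structure of the
full-size protocol (35 subjects, 6 blocks, 5 groups of 7) is available by
passing the corresponding `SimConfig`/`SchemeConfig`.

## What the synthetic conditions can and cannot show

Two comparative findings from recorded EEG should *not* be expected to
reproduce on this generator, and the corresponding end-to-end tests treat
them as open questions rather than guarantees:

- **CNN vs CCA.** The generator emits literal sinusoid stacks in additive
  colored noise — exactly the signal class for which CCA with matched
  sine/cosine references is the matched-subspace detector. On such data
  CCA sits at or near the detection ceiling (it saturates on the
  high-SNR occipital channel and stays strong at the ears), and no
  trained classifier can systematically beat it. The advantage of learned
  classifiers on recordings comes from non-sinusoidal response waveforms,
  non-stationarity and artifacts, none of which the generator models.
- **Subject-dependent vs subject-independent training.** With magnitude
  spectrograms of rectangular, integer-frequency frames, the
  class-discriminative feature — which frequency bins carry energy — is
  identical for every simulated subject: the subject-specific phases are
  provably erased by the magnitude, and the gain and tilt perturbations
  are mild. Pooled training therefore transfers almost perfectly to
  held-out subjects, and the two schemes land within noise of each other.
  The large scheme gap seen on recordings reflects genuinely
  subject-specific spectral structure that this generator only hints at.

What the synthetic conditions *do* establish: the channel-quality ordering
(occipital above fused binaural above single-ear average) under the
calibrated 7.54 dB / 0.35 dB contrast, exact recovery of planted fusion
maps, convergence of the classifier on separable data, and all geometric
and metric contracts.

## Known limitations

- Absolute accuracies on synthetic data are not comparable to recordings;
  only orderings and mechanism are meaningful.
- The MAT adapter expects the channels × samples × targets × blocks layout
  with explicit channel/frequency tables; 64-channel benchmark files must
  carry (or be given) channel names.
- The CNN is single-threaded numpy; it is sized for these 125×W images,
  not a general-purpose deep-learning stack.
- Dropout ties all three layers to the single configured rate, and pooling
  geometry is fixed per width as described above.
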