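# Methods

This note documents the models, conventions and numerical choices behind
`myofatigue`: what the pipeline computes, what the synthetic cohort does and
does not emulate, and where genuinely open design decisions were settled.

## Problem

Cyclic manual lifting drives skeletal muscles into fatigue. Two biosignals
track this: surface electromyography (sEMG, electrical, ~20–500 Hz) and
mechanomyography (MMG, mechanical vibration recorded by accelerometer,
~10–50 Hz). Both degrade under different field conditions — sweat corrupts
sEMG, external vibration corrupts MMG — which is the motivation for fusing
them. The pipeline turns 12 channels (6 muscles × 2 modalities) into a
six-level whole-body fatigue label per time window and trains multi-class
classifiers to predict that label from per-window spectral features.

## Feature model

Each channel is band-pass filtered (fourth-order Butterworth, 20–500 Hz sEMG
/ 10–50 Hz MMG, second-order sections, forward–backward so the filter is
zero-phase and window boundaries stay aligned; reflective padding of at least
three low-frequency filter lengths suppresses startup transients). The trial
is split into 120 equal windows; any remainder samples are dropped from the
end. Per window the power spectral density is the raw periodogram

    PSD(f_k) = |X(f_k)|² / T,

with `X` the finite-time Fourier transform (Δt-scaled DFT) and `T` the window
duration; the one-sided density doubles interior bins so it integrates to the
window's mean power (Parseval). The mean power frequency is the
power-weighted mean

    MPF = Σ f·PSD(f) / Σ PSD(f)

on the discrete grid. Per channel the 120 MPF values are min-max normalized,
`y = (x − x_min)/(x_max − x_min)`, making sEMG (tens of Hz) and MMG (a few
Hz) commensurable. No Welch averaging or taper is applied by default because
the plain periodogram is the definition being implemented; a Hann-taper
option exists for robustness studies. Full-wave rectification is implemented
as the post-filter "correction" step but is **not** applied before spectral
features by default: rectification distorts the spectrum that the MPF is
computed from, and the fatigue trend lives in the un-rectified band. A config
switch (`preprocess.rectify_before_features`) restores rectified-input MPF
for sensitivity analysis.

## Staging and fusion

The fatigue trajectory of a muscle is read off the *peak envelope* of its
normalized MPF series: the piecewise-linear interpolation through the strict
local maxima plus both endpoints. The global envelope peak `p*` (first index
on ties) anchors six ordinal stages:

| stage | condition |
|-------|-----------|
| 0 | before the ascent of the MPF begins |
| 1 | ascent through the peak |
| 2–5 | envelope has dropped ≥ 5 / 10 / 15 / 20 % below its peak |

Drops are fractions `(peak − envelope)/peak` of the normalized envelope, and
labels carry their running maximum forward (fatigue does not regress within a
trial). The ascent start is the last pre-peak index at which the underlying
series attains its minimum: the envelope itself is a single rising chord
before the peak and has no interior minima, so the series minimum is the only
data-driven marker of where growth begins.

Whole-body fusion applies two rules per window, in order, to the 12 muscle
labels: (1) if at least four muscles currently share a stage, the body takes
the highest such stage (ties between eligible stages resolve toward the more
fatigued state; if no stage has four muscles the previous body state carries
forward); (2) if afterwards any muscle sits at least two stages above the
body state, the body state is promoted by one level. The result is clamped to
be non-decreasing. Rule (2) is one reading of an ambiguous verbal rule
("greater … in two stages"); it is isolated in a single predicate function so
alternative readings are swappable. The body state starts at 0 and can never
exceed the highest muscle label.

## Classifiers

Three dataset variants are assembled — 6-dim sEMG, 6-dim MMG, 12-dim fused —
with one row per (subject, window), features in [0, 1] and the fused body
state as label. 20 % of rows are randomly held out (plain random draw; only
if a class vanishes from the training rows is the split re-drawn stratified,
and if a singleton class makes stratification impossible one row of each
missing class is moved from test to train deterministically).

Four families:

* `svm_rbf` — RBF-kernel SVM (C = 10, gamma scaled).
* `mlp` — back-propagation MLP with three hidden layers of 180 units.
* `mlp_att` — a small transformer-style encoder over the feature row,
  trained jointly with a one-hidden-layer head.
* `svm_att` — the same encoder pre-trained with its head, then frozen; the
  mean-pooled encodings feed an RBF SVM.

The encoder treats each feature dimension as one token: the scalar is mapped
to a `d_model = 8` vector by a learned per-dimension scale and bias plus a
learned position embedding, then passes through 2 layers of 4-head scaled
dot-product attention, `softmax(QKᵀ/√d_k)V`, each with a position-wise
feed-forward sublayer (width 16) and residual connections. No layer
normalization is used: at this width plain residuals train stably and keep
the arithmetic transparent. Forward pass, backpropagation and Adam
(lr 5·10⁻³, batch 256, 120 epochs) are implemented directly on numpy arrays;
the hand-written gradients are verified against finite differences in the
test suite. Width, depth, head count and pooling are recorded in config.
Because `mlp_att` and `svm_att` pre-train the identical encoder on the same
rows with the same seed, the pipeline trains it once and shares it between
the two families; results are identical to training twice.

## Evaluation

The 6×6 confusion matrix yields per-class one-vs-rest tallies and the five
metrics (accuracy, precision, recall, specificity, F1). The multi-class
summary is the macro average over classes whose denominators are defined;
undefined per-class values are reported as undefined, not zero, and micro
averages are emitted alongside for transparency. Each (variant, family)
combination is repeated 10 times with derived seeds — both the split and the
model initialization are re-drawn — and reported as mean ± s.d. Family
comparisons use a two-sample Welch t-test (pooled-variance option in config)
at α = 0.02; two zero-variance samples with equal means give t = 0, p = 1 by
convention.

## Synthetic cohort

No recordings are distributed with the protocol this pipeline targets, so a
generator produces a cohort with known ground truth: 16 subjects, lifting at
180 BPM with one movement per 4 beats (movement period 1.333 s), 6 muscles
with sEMG at 2000 Hz on one body side and MMG at 400 Hz on the other,
300 s per trial (a realistic lifting-to-exhaustion session; 120 windows of
2.5 s, each holding ≥ 2 cycles of the lowest in-band frequency).

Each channel is Gaussian noise shaped in short-time blocks (square-root-Hann,
50 % overlap-add, which keeps sample variance stationary) so that its
spectral centroid follows a piecewise-linear MPF trajectory: a shallow
warm-up dip (5 % below baseline) to the rise onset, a linear ascent to the
peak, then a linear decline of a fixed fraction of the peak per second.
Muscles are staggered (rise onset 0.26–0.34, peak 0.56–0.65 of the trial,
total decline 30–36 % of peak) and per-subject jitter (±2 %) varies centers
and timing. Defaults place sEMG centers at 94–118 Hz and MMG at 32–47 Hz.
Movement cycles amplitude-modulate the signal with a raised-cosine burst
(floor 0.3), and a white noise floor of 0.08 relative amplitude is added.

Two deliberate departures from physiological realism, both documented here:

* **Spectral width.** The per-channel spectra are narrower (PSD σ = 4 Hz
  sEMG, 1.2 Hz MMG) than real surface EMG, which spreads over ~100 Hz. A
  single-window periodogram centroid of a broadband process is intrinsically
  noisy; the narrow bands keep the per-window MPF estimator's standard error
  around 1 Hz so that staging recovery is a sharp, testable property. Real
  recordings would need envelope-level smoothing beyond what the peak
  envelope provides.
* **The warm-up dip** exists so that the ascent onset is a unique, estimable
  minimum; with a perfectly flat baseline the stage-0/1 boundary would be
  unidentifiable from data.

Ground-truth stages come from applying the staging definition (envelope +
threshold scan, an independent plain-loop implementation) to the noiseless
trajectory, and the true body state from fusing the 12 noiseless stage
series. On noiseless trajectories the estimation path reproduces the truth
exactly; under the default noise it recovers the peak window to a median
error well inside ±3 windows and ≥ 90 % of per-window stages.

Complementary artifacts (off by default, enabled for the fusion experiment)
emulate the field conditions that motivate fusion: *sweat* attenuates random
~15 s segments of sEMG (×0.35) and overlays broadband noise (1.5× RMS);
*vibration* injects short (0.12 s) high-amplitude (8× RMS) transient bursts
into MMG at 0.12 events/s. Artifacts draw from a dedicated random stream so
toggling them never changes the underlying signal. Because each contamination
touches only one modality, single-modality feature sets lose accuracy in
contaminated windows while the fused set retains clean channels — the
fusion-benefit property the repeat experiment quantifies.

What passing tests on this cohort do **not** show: performance on real
recordings (real sEMG is broadband and nonstationary within windows, real
fatigue onset is not piecewise linear, real artifacts are not independent
across channels), nor the absolute accuracy figures attainable on any
particular empirical dataset.

## Numerical and protocol choices

* Problem sizes: the repeat experiments use 10 seeds of the 16-subject
  cohort; the recovery experiment uses one subject (12 channels) per seed.
* All randomness flows from integer seed sequences through
  `numpy.random.default_rng`; identical (config, seed) reproduce every
  artifact byte-for-byte (run logs record seeds, config hash and row counts,
  never wall-clock times).
* Degenerate inputs are explicit errors: zero-power windows, constant MPF
  series, single-class training sets, filters whose upper edge reaches
  Nyquist. A flat envelope stages as all-zero with a warning.
* Ties: first index wins at envelope plateaus; the highest eligible stage
  wins in fusion condition (1).
* The 120 windows are uniform over the whole recording (no cycle alignment);
  remainder samples are dropped at the end.

## Known limitations

* The generator's trajectory family (piecewise linear with one peak) cannot
  express plateaus, partial recovery or non-monotone fatigue.
* Stages 2–4 occupy narrow time bands by construction, so those classes are
  rare in the datasets; per-class metrics for them are unstable and the
  macro average reflects that. This mirrors the acknowledged sparsity of
  transitional fatigue states in the protocol being modeled.
* The attention families' accuracy depends on a fixed, small training budget
  chosen for desk-scale runtimes; they are not tuned per dataset.
* Fusion condition (2) implements one reading of an ambiguous rule; the
  predicate is isolated so alternatives can be swapped and compared.
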