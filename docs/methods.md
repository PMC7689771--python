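# Methods

`mwdecode` implements an alpha-band EEG decoding analysis that asks
whether classifiers trained to detect task demands or vigilance can
predict self-reported mind-wandering, together with a synthetic-EEG
generator that provides data with the statistical structure the
analysis assumes. This note documents the models, the parameter
choices, and the limits of what the synthetic experiments can show.

## The decoding analysis

**Trial labelings.** Three binary labelings of the visual search (VS)
trials: *demand* (counting blocks = high vs. non-counting = low),
*vigilance* (per-participant chronological median split: first half =
high), and *self-report* (the three trials preceding each thought probe
inherit its −5…+5 rating; negative = mind-wandering, positive = on-task,
zero excluded). SART trials are labeled by self-report only. Throughout
the package the positive class (label 1) is the "off" state
(mind-wandering / low demand / low vigilance).

**Signal chain.** Mastoid-average re-reference → 0.1–42 Hz band-pass →
downsampling 512→256 Hz → 4-s epochs ([−1, +3) s around stimulus onset)
with a −200–0 ms baseline → alpha-band filtering (below) → one group ICA
over all participants' alpha oscillations concatenated in time → per
trial, the squared magnitude of each component activation's analytic
signal, averaged in twelve 100-ms bins spanning −600…+600 ms:
12 bins × 32 components = 384 features. Raw (non-baseline-corrected)
power enters the features; percent-change ERD traces exist for reporting
only.

**Alpha kernel.** A least-squares linear-phase FIR with a "plateau"
ideal response: 1 on 8.5–12 Hz, 0 elsewhere, linear ramps over
transition bands 20% of each band edge wide (6.8–8.5 and 12–14.4 Hz).
Length is the smallest odd integer covering three cycles of 8.5 Hz at
256 Hz (91 taps). The raw least-squares kernel peaks at gain 1.099
inside the passband, so it is normalized to unit peak gain; the gain at
10 Hz is then 0.990. The design figure of merit (`design_sse`) is the
sum of squared deviations between the max-normalized kernel spectrum and
the ideal response, read off at the six design frequencies (DC, the four
band edges, Nyquist) on the kernel's own FFT grid; it evaluates to 0.10.
A dense uniform grid would give a figure an order of magnitude larger —
the six-point band-edge convention is the one under which the published
0.1 is reproducible, so it is the one implemented.

**Filter application.** The alpha FIR is applied forward–backward with
one kernel length of reflection padding, so bin powers are not phase
shifted (a causal application would delay the envelope by ~175 ms, more
than a bin width). The broadband 0.1 Hz high-pass is a zero-phase
spectral filter (raised-cosine ramp from DC to the cutoff) rather than
an IIR: at 0.1 Hz a Butterworth's poles sit so close to the unit circle
that forward–backward filtering rings visibly across a whole recording,
while an equivalent FIR would be tens of seconds long. The 42 Hz
low-pass is an order-8 Butterworth run forward–backward (>20 dB down at
50 Hz).

**Group ICA.** FastICA with the tanh (logcosh) contrast on the
temporally concatenated 32-channel alpha oscillations of all
participants, seeded, with components ordered by explained variance of
the concatenated signal and signs fixed so each component's
largest-magnitude mixing weight is positive. The estimation may thin the
concatenated series (default: every 2nd sample) — ICA statistics
converge long before that density matters — but activations and features
always use the full-rate epochs.

**Classifier protocol.** RBF-SVM with C = 1 and γ = 1/(feature
dimension) (1/384 for full models, 1/12 for single-component models).
Per training fold: per-feature z-transform estimated on the training
sample only and applied frozen to validation/test data; random
over-sampling of the minority class to parity (majority indices
preserved; resampling seeded). Validation combines an outer
leave-one-participant-out loop (the reported accuracy) with a
diagnostic inner stratified 10-fold CV; each outer-fold model also
predicts the self-report-labeled SART trials (the across-task
transfer), and the reported transfer is the average over outer folds.

**Chance statistics.** Accuracies are compared with the data-size
corrected chance level: the binomial inverse-CDF threshold
`binoinv(1 − α, n, ½)/n`, the largest accuracy still compatible with
guessing at level α. For n = 11,436 (pooled VS trials) this is 50.77%,
for n = 1,494 (pooled SART self-report trials) 52.14%. Group-level
decisions use one-sample t tests of fold accuracies against this
threshold (two-sided by default; the per-component feature tests use
one-sided "greater", since below-chance prediction is not meaningful
there, with no multiple-testing correction by default and
Bonferroni/FDR switches available). Sensitivity and specificity
(mind-wandering = positive) accompany every report because raw accuracy
on imbalanced self-report test sets is inflated toward the majority
class rate — see "Caveats" below.

**Source localization.** Component topographies (mixing-matrix columns)
are fitted with equivalent current dipoles in a three-shell concentric
sphere (radii 8.0/8.5/9.2 cm; conductivities 0.33/0.0042/0.33 S/m;
Legendre series truncated at 60 terms, converged to <0.1% for any
plausible source depth). The fit minimizes residual variance
rv = ‖observed − modeled‖²/‖observed‖² by an 11³ grid search inside the
brain shell followed by Nelder–Mead refinement from the three best grid
points, with the moment solved linearly at every candidate position.
Bilateral fits constrain two dipoles to mirror positions across the
midsagittal plane (x ↔ −x) with free moments solved jointly; x = 0 is
admissible, so a midline pair may coincide in position with different
moment orientations. The spherical model replaces a boundary-element
head model deliberately: it is closed-form and dependency-free, and
recovery-style validation (median position error < 3 mm noiseless on
randomly placed sources) is what the synthetic setting can support.
No anatomical atlas lookup is attempted.

## The synthetic experiments

**Design.** The generator's defaults define the reference study design:
30 participants; a VS
task of 21 trials × 10 blocks per condition, conditions alternating in
A-B-A-B sessions counterbalanced by participant parity; a SART of 12
blocks, each 2–7 shuffled repetitions of the digits 1–9 (so the NOGO
digit "3" appears on exactly 1/9 ≈ 11% of trials); a probe at the end
of every block. Timing: fixation U(0.5, 1.5) s, 2-s count instruction
(counting blocks), 4-s search panel, log-normal response latencies
(medians 0.65 s counting / 0.48 s non-counting, σ = 0.3 — event timing
only, no behavioral realism claimed), ITI U(0.5, 1.5) s; SART digits
250 ms + 1,750 ms blank; 512 Hz sampling.

**Latent states and ratings.** Demand follows the block condition;
vigilance is the chronological half; attention (on-task vs.
mind-wandering) is drawn per block. Probe ratings come from a noisy
monotone link: `rating = round(clip(g·sign + N(0, σ), −5, 5))` with
sign +1 for on-task, g = 2.5, σ = 1.5, giving ≈ 7% "0" (excluded)
ratings and ≈ 2% sign flips — the label noise a self-report instrument
plausibly has.

**Balanced attention assignment.** By default the mind-wandering blocks
(a fixed round(rate·n) of them, base rate 0.35) are spread as evenly as
possible across the design cells (condition × half in VS, half in
SART), instead of i.i.d. draws. At study scale the difference is
negligible, but at desk scale i.i.d. draws leave chance correlations
between attention and demand/half large enough that a demand classifier
can genuinely learn the attention source — the "disjoint" null would
not be a null by construction. A flag restores i.i.d. draws.

**EEG.** Each source is a dipole inside the brain shell oscillating at
a fixed alpha frequency (8.5–12 Hz, small seeded jitter per experiment)
whose scalp pattern comes from the package's own forward model,
normalized so `baseline_amp` is the pre-stimulus peak scalp amplitude in
µV. After every stimulus onset the source amplitude is multiplied, for
1.2 s with 100-ms cosine ramps, by a state-dependent factor (<1 =
event-related desynchronization); factors multiply across latent
factors and may be scoped to one task (`"attention@SART"`). A slow
(<0.3 Hz) seeded amplitude fluctuation (±25%) makes sources
statistically independent. Noise is per-channel 1/f ("pink") background
(RMS 8 µV) plus white sensor noise (RMS 2 µV); stereotyped frontal
blink transients are available but off by default (manual ocular-artifact
removal is out of scope, so clean defaults keep the chain testable). Channel-averaged
spectra show the alpha peak above the 1/f trend.

**Source layouts.** The *disjoint* layout has two demand-modulated
parietal sources (ERD multipliers 0.55 high / 0.90 low demand, plus a
task-generic 0.70 on SART trials — posterior alpha desynchronizes in
any attended task, and without this the demand model degenerates to a
constant prediction on the SART), a deep central vigilance source
(0.60/0.95), one left-temporal attention source (0.50 on-task / 1.0
mind-wandering, 9 µV — the strongest contrast, so the reduced-scale
positive control has adequate power), and two unmodulated background
alpha generators. The *shared* layout replaces the demand/vigilance
generators with sources shared across tasks: driven by demand (or
vigilance) during VS and by momentary attention at matching contrast
during the SART — the mechanism under which a demand or vigilance
classifier *should* transfer.

## Reduced problem sizes

The dissociation experiment runs at 6 participants with 60 VS trials
(20 blocks of 3) and 12 single-repetition SART blocks (108 trials),
five seeds for the disjoint layout and one for the shared layout; the
other suites use a few participants and tens of trials. These sizes
are the package's chosen desk-scale study conditions; all thresholds
are computed from the data actually generated, never imported from the
full-size reference counts.

## Caveats on chance levels at desk scale

Two properties of the protocol matter when reading the results:

1. **Imbalanced self-report test sets inflate raw accuracy.** Most
   probes are rated on-task, and an uninformative SVM drifts toward the
   majority class even after balanced training (duplicated minority
   samples carry less effective diversity). Sensitivity/specificity
   expose this; the null-calibration tests therefore check *balanced*
   accuracy for the self-report scheme.
2. **Self-report labels cluster by probe.** The three trials before a
   probe share its label and its latent state, so the effective sample
   size of a transfer accuracy is the probe count, not the trial count.
   The corrected chance level at the trial count is anticonservative at
   desk scale; the dissociation test judges "at chance" against the
   probe-count band and "above chance" against the (stricter-to-beat in
   practice, and conventionally reported) trial-count threshold.

## What passing tests do and do not show

The generator produces exactly the covariance structure the pipeline
assumes: dipolar narrowband sources, multiplicative state modulation,
stationary 1/f noise, honest labels up to a simple noise model. Real
EEG has none of these guarantees — non-stationary artifacts, volume
conduction from many correlated sources, reference drift, latent states
that are neither block-constant nor binary. Passing the dissociation
test shows the *pipeline* draws the right conclusion when the ground
truth is disjoint or shared; it says nothing about whether any real
dataset is one or the other.

## Numerical choices

* Epoch windows are [−1, +3) s at 256 Hz (1,024 samples); the baseline
  is [−0.2, 0) s; 100-ms bins are defined by time masks (25/26 samples
  alternate, since 0.1 s is not an integer sample count at 256 Hz).
* Spherical-spline channel interpolation uses the standard 4th-order
  spline (m = 4, 50 Legendre terms, ridge 1e-5).
* FFTs on arbitrary-length recordings are padded to fast lengths.
* Inner 10-fold partitions are stratified with seeded shuffling; fold
  seeds derive from the outer seed with fixed prime offsets.
* Zero-variance features are dropped (and counted in the model
  manifest) before the z-transform; γ uses the surviving dimension.
* Dipole grid candidates and refinement iterates are rejected outside
  95% of the brain radius; electrode positions are projected radially
  onto the scalp shell before fitting.

## Known limitations

* The spherical head model supports recovery-style validation only; no
  claim about anatomical localization accuracy is made or tested.
* The generator's attention latent is block-constant; drifts within a
  block, or states uncoupled from probes, are not modeled.
* FastICA on narrowband signals separates sources by their envelope
  structure; two sources with identical frequency *and* envelope
  statistics are not identifiable and will mix.
* EDF export is not provided; recordings round-trip through a raw
  float32 + JSON sidecar format instead.
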