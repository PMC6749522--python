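# Methods

This note records the models, parameter choices and numerical conventions
behind `stopplv`, and what the synthetic validation does and does not show.

## Behavioural model

Stop-signal sessions follow the standard independent horse-race account: on
every trial a go process finishes at a log-normal reaction time
(`go_mu = ln 450`, `go_sigma = 0.2` on the log-ms scale, i.e. a ~450 ms
median), and on stop trials a stop process finishes SSRT ms after the stop
signal (`ssrt_ms = 200`, Gaussian jitter SD 20 ms, truncated at 1 ms).  The
trial is a successful stop (SS) iff the go finisher is slower than
SSD + SSRT.  The one-up/one-down staircase (start 250 ms, step 50 ms,
clamped to [50, 1000] ms) then tracks the SSD at which P(SS) = 0.5; with the
defaults the fixed point sits near 250 ms (median go RT minus mean SSRT),
well inside the bounds.  The task itself provides no response model, so the
race model is generator plumbing: its only requirements are positivity of
all durations and staircase convergence, both property-tested.

Session composition is exact, not sampled: `round(n_trials x
stop_fraction)` stop trials (25 of 100 by default) at randomized positions,
split as evenly as possible between the two go shapes, with the odd trial
assigned to a random shape.  The shape→hand mapping is square→left,
circle→right and is configurable.  `stop_fraction` must lie strictly in
(0, 1); an all-go "session" is not a valid stop-signal design.

## Synthetic EEG

Epochs are 32 channels (a 10-20/10-10 montage subset) x 750 samples: the
half-open window [-200, 1300) ms around stop-signal onset at 500 Hz.  Three
ingredients:

- **Background noise**: independent white noise per channel, SD 2.5 µV.
  Real EEG noise is colored and spatially correlated through the volume
  conductor; white noise is deliberately chosen so uncoupled pairs sit at a
  known chance floor.
- **P300**: a Gaussian bump (peak 300 ms, SD 55 ms) on the frontal-central
  channels (FZ maximal), 8 µV on failed stops vs 5 µV on successful stops.
  The FS > SS ordering is an enforced invariant of the configuration.
- **Phase coupling**: for each configured (condition, pair), two
  oscillations sharing a common phase track (instantaneous frequency
  wandering in the 6–14 Hz carrier band) plus independent per-signal
  Gaussian AR(1) phase noise, at 12 µV.

### Calibrated phase-noise construction

For Gaussian phase noise the resultant of the injected phase difference has
the closed form `exp(-(sigma1^2 + sigma2^2)/2)` regardless of
autocorrelation.  The *measured* PLV, however, is taken after 1–50 Hz
band-pass filtering and Hilbert demodulation, which attenuate the faster
part of the phase noise (it leaks into the instantaneous amplitude), so the
noise SD that realises a requested measured PLV is larger than the closed
form suggests.  `coupled_pair_signal` therefore solves the noise scale
against a Monte-Carlo calibration curve — mean demodulated PLV as a function
of noise SD, computed once per configuration with a fixed internal seed and
cached — and interpolates.  Verified behaviour: targets in [0.3, 1.0] are
recovered within ±0.02 on average through the standard pipeline; target 0
saturates at the construction's decorrelation floor (~0.2 over a 150-sample
window), since a finite phase-noise window never averages to exactly zero.
Replicate-mean measured PLV is monotone in the target.

The AR(1) correlation time is 4 samples: short enough that a 150-sample
window holds many effectively independent phase-difference samples, long
enough for clean demodulation.  The per-trial PLV estimator's SD is
bandwidth-limited (the 1–50 Hz filter caps how fast the phase difference
can decorrelate) at roughly 0.06–0.11 for PLVs of 0.9–0.7; planted
contrasts are therefore placed in the upper coupling range, where the
estimator is tightest.

The default coupling layout mirrors the qualitative structure being
emulated — coupling higher on failed than successful stops, strongest
stop-outcome contrasts at temporo-occipital pairs (T8-O2 for the left hand,
T7-O1 for the right), and a hand contrast among successful stops at T8-O2 —
with values in the 0.72–0.91 range typical of task EEG.  Pairs without an
entry carry noise only.

### What passing tests do not show

The generator omits volume conduction, 1/f spectra, eye/muscle artifacts
(beyond injected test transients), inter-subject variability in coupling,
and any hand dependence of the P300.  Pipeline validation on this ground
truth demonstrates correctness of the operations, not expected performance
on real recordings.

## Preprocessing

4th-order Butterworth band-pass (1–50 Hz) applied forward-backward.
Zero-phase filtering is essential here: one-pass IIR phase distortion is
frequency-dependent and would bias inter-electrode phase differences.  The
effective magnitude response is the squared single-pass response, which the
tests check against the designed transfer function.  Down-sampling
(1000 → 500 Hz) uses an anti-aliased FIR decimator (keep-every-qth
convention, DC-exact away from edge transients).  Sample windows are
0-based and half-open with time 0 at stimulus onset; an event at sample
1000 yields the epoch [900, 1650) at 500 Hz.  Baseline correction subtracts
the per-trial/channel mean over [-200, 0) ms.

Artifact rejection replaces manual component inspection with an automatic
criterion: FastICA on the concatenated epochs, zeroing components whose
kurtosis or log-variance z-score (across components) exceeds 3, then
back-projection.  `method="none"` is the default for synthetic data, which
is generated clean.  Decomposition failure degrades to a warned
pass-through rather than an error.

## ERP analysis

Condition ERPs average within subject first, then across subjects; the P300
measure defaults to the window mean over 250–400 ms (no standard
quantification window exists; the peak mode is available).  The SS-vs-FS
contrast is tested per time sample with the two-sided Wilcoxon signed-rank
test at alpha = 0.05 with **no multiplicity correction** — this mirrors the
per-sample asterisk convention of ERP figures and is anti-conservative; a
sample where all paired differences vanish gets p = 1.  At the study's
n = 12 the implementation agrees with exact enumeration of all 2^n sign
assignments.  Testing requires at least 5 pairs.

## PLV features

Eq. for the statistic: `PLV = |mean_k exp(i(φ1(k) − φ2(k)))|` — the
modulus of the mean unit phasor of the signed phase difference (the
standard Lachaux definition).  A formulation with the absolute difference
inside the exponent and no outer modulus does not produce a real number in
[0, 1] and is not implementable as stated; the implemented form satisfies
the documented 0–1 normalization and the "identical phases → 1" anchor.

One PLV per trial per (pair, band) over 1–300 ms post-stimulus (150 samples
at 500 Hz).  Per-trial features are required for trial-level
classification.  The default band set is the single 1–50 Hz wideband — the
same band the preprocessing uses before Hilbert demodulation — because a
300 ms window in a narrow sub-band contains on the order of one independent
phase sample (time–bandwidth limit), too few for single-trial features.
Five canonical sub-bands (1–4, 4–7, 8–12, 13–30, 30–50 Hz) are available
via `bands=CANONICAL_BANDS` for spectrally resolved analyses and to give
forward selection a nontrivial space.  Optional z-normalization scores each
feature column against the same feature computed on the pre-stimulus
[-200, 0) ms window; zero-SD baseline columns map to 0 with a warning.

## Classifiers

All four are implemented from their definitions and cross-checked against
independent oracles (closed-form Gaussian discriminant, brute-force vote,
direct kernel summation, sklearn).  Priors come from training frequencies.
Covariances are shrunk toward their diagonal, `S ← (1−λ)S + λ diag(S)` with
λ = 0.01 by default, because per-fold class sizes are small; a singular
covariance at λ = 0 raises an error that names the remedy.  Parzen
bandwidth maximizes the leave-one-out log-likelihood of the training set
over a 16-point log-spaced grid spanning 0.05–5 x the mean feature SD,
refined once around the winner.  Ties anywhere (KNN votes, equal
discriminants) resolve to the class of the single nearest training
neighbour, then the lexicographically smaller label — deterministic by
construction.

## Evaluation

LOOCV supplies the headline confusion-matrix metrics; repeated stratified
90/10 splits (20 repeats) supply the mean ± SD accuracy column.  Both
protocols appear in the evaluation design and are reported side by side.
Forward selection greedily adds the feature minimizing LOOCV error of the
augmented set (ties → lowest column index) and stops at `max_k` or when no
candidate strictly improves; the error along the trace never increases.

Undefined metric ratios (zero denominators) are reported as absent, never
as 0.  Reported tables truncate values at two decimals (16/18 → 88.88%,
8/9 → 0.88) and derive the printed FPR from the truncated specificity
(0.88 → 0.12); full precision is retained internally.

**A caution on LOOCV at chance.**  Leave-one-out with mean-based
classifiers is pessimistically biased on uninformative features: removing a
point shifts its own class mean away from it, and when the class means
nearly coincide this systematic effect dominates, driving accuracy well
below — in degenerate cases far below — 50%.  Chance-level checks in the
test suite therefore assert the scientifically meaningful direction (no
cell exceeds the upper 99% binomial bound) and treat sub-chance LOOCV
accuracy as expected behaviour, not an error.

## Hierarchy

Trials from all subjects are pooled per stage (a per-subject breakdown can
be obtained by filtering the EpochSet).  Each stage is a binary problem
with a fixed positive class — FS in the two stop-outcome stages, RHR-SS in
the hand stage — so sensitivity and PPV are consistently defined.  Feature
selection, when enabled, runs independently per (stage, pair, classifier)
cell.  Stages with fewer than `min_trials` (default 4) per class are
skipped with an explicit warning.  The classifier ANOVA per stage uses the
4 x 8 grid of per-pair LOOCV accuracies, giving df (3, 28).  Everything is
deterministic given the configuration and seed; report rendering is
idempotent (byte-identical on re-render).

## Problem sizes used in validation

The test suite validates the pipeline at 40–120 trials per stage, 150–200
Monte-Carlo replicates for calibration checks, and a 12-subject default
study (300 pooled stop trials) for the worked example — sizes at which
every statistical check has adequate power while the whole suite stays
fast.

## Known limitations

- EDF files can be read (via MNE) but not written; the native container is
  npz + CSV.
- The ICA rejection criterion is intentionally simple (kurtosis/variance
  z-scores); it catches spike-like and high-variance artifact sources, not
  stereotyped ocular topographies.
- PLV on wideband signals conflates coupling across the whole 1–50 Hz
  range; the sub-band option trades that specificity against single-trial
  estimator variance.
- The pointwise signed-rank masks are uncorrected for multiple comparisons
  by design; treat them as descriptive.
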