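# Methods

## The decoding problem

A cue-paced motor-imagery calibration run presents a fixation cross at t = 0
of each 10-s trial cycle, an imagery cue from 2 to 6 s, and a break from 6 to
10 s. The decoder sees a band-passed multichannel EEG epoch per trial and
must separate two categories — imagery vs rest, or left- vs right-hand
imagery. The scientific question the package quantifies: how does the length
of the analysis window (0.5, 1, 2 or 4 s) move classification accuracy and
the false-positive ratio, the two quantities that jointly determine whether
an online system is both correct and responsive?

The mechanism under study is statistical, not neural: CSP classification
consumes per-window variance estimates of spatially filtered signals. For a
stationary signal the standard error of a log-variance feature scales as
1/√(window samples) (verified as a property test), so shorter windows mean
noisier features, lower accuracy and more false positives — unless the
extra trials-per-second or non-stationary structure compensates, which is
precisely the trade-off worth measuring.

## Synthetic sessions

`synthdata.generate_session` builds a session from four additive parts, per
channel:

1. **Oscillatory sources.** Two statistically independent sources, each a
   sum of band-limited Gaussian noise in the mu (8–13 Hz) and beta
   (13–30 Hz) bands with a 2:1 mu:beta power ratio, unit total variance.
   Band-limited noise rather than sinusoids keeps per-trial covariances full
   rank, which CSP requires.
2. **Topographies.** Each source projects through a fixed unit-norm channel
   weight vector — a Gaussian bump (width 0.35 head radii) over nominal
   2-D 10-20 coordinates, centred at C3 (left motor cortex) and C4 (right).
   The default montage is the 11-electrode sensorimotor set FC3, FC4, C3,
   C4, CP3, CP4, CPz, C1, C2, C5, C6.
3. **ERD/ERS modulation.** While the cue is on (2–6 s of the cycle), the
   source contralateral to the imagined hand is scaled in power by
   1 − `erd_depth` and the ipsilateral source by `ers_gain` (default 1, i.e.
   ERS off). The amplitude envelope uses 0.25-s raised-cosine ramps placed
   inside the cue interval so no modulation leaks into the break. In
   imagery-vs-rest mode the cued hand is the right hand by convention, so
   the C3 source desynchronizes.
4. **Noise.** Per-channel 1/f^γ background (γ = `background_exponent`,
   default 1, synthesized by FFT spectral shaping, unit variance) plus a
   white sensor-noise floor at `sensor_noise_db` (default −10 dB) relative
   to the background.

`snr_db` (default 5 dB) fixes each source's total scalp-projected variance
relative to the per-channel background variance; because the sources live
inside the 8–30 Hz band while the background is broadband, the effective
in-band SNR after filtering is roughly 6 dB higher at the peak electrode.
The defaults (35 trials per class, 256 Hz, ERD depth 0.5, 5 dB SNR) define
the cohort used everywhere, and were chosen so that default accuracy sits
mid-range between chance and ceiling — the regime where duration effects
are actually visible.

Rest epochs in imagery-vs-rest mode are cut from the break intervals: a
"rest" event is placed 4 s after each fixation cross so that the standard
2–6 s segmentation lands on the 6–10 s break, giving one 4-s rest epoch per
cycle and balanced classes by construction.

**What the simulator does not emulate:** volume conduction beyond fixed
linear mixing, EOG/EMG artifacts, within-session drift or fatigue,
trial-to-trial ERD variability beyond the stochastic source amplitudes, and
any between-subject structure other than the seed. Passing tests therefore
demonstrate that the pipeline recovers known band-power structure and that
the window-duration mechanism behaves as predicted — not that the same
effect sizes would be measured on patient data.

## Preprocessing

Band-pass: Butterworth 8–30 Hz of order 2, applied causally (forward only)
because the framing is a real-time system; a `zero_phase` flag provides
forward-backward filtering for offline use (doubling the effective order —
the causal design keeps ~81% of white-noise power in band, the zero-phase
variant ~94%). Epochs are 2–6 s after each event (1024 samples at 256 Hz);
truncated trailing trials are dropped with a warning. The eight windows are
anchored at the epoch start and tile forward — 0.5-s at {0, 0.5, 1, 1.5} s,
1-s at {0, 1} s, 2-s and 4-s at 0 s — using half-open sample intervals so
non-overlap is exact. Anchoring at the imagery onset puts the short windows
on the earliest ERD, where a responsive system would operate; placement is
overridable.

## CSP

Per-trial covariances are mean-centred and trace-normalized before
averaging into class covariances (the standard guard against amplitude
outliers). The joint diagonalization is solved by whitening: eigh on
C = C₁+C₂ gives the whitener P = U diag(d)^{-1/2}; eigh on PᵀC₁P gives
rotation V and eigenvalues λ ∈ [0,1]; W = PV. This double symmetric
eigendecomposition is numerically stabler than a direct generalized solve
and is validated against `scipy.linalg.eigh(C₁, C₁+C₂)` in tests. Exact
rank deficiency of C raises an error naming the dead dimensions; an
ill-conditioned but full-rank C (condition > 1e8) receives a logged ridge
of 1e-10·trace. Spatial patterns are computed as (C₁+C₂)W, which equals the
inverse-transpose of W under the identity constraint.

Features use m = 3 filter pairs (6 features for 11 channels; the filter
count is configurable) and the normalized log-variance
log(vᵢ/Σv) — scale-invariant, the common published variant.

A note on invariances: with per-trial trace normalization, CSP eigenvalues
and features are exactly invariant under *power-preserving* (orthogonal)
channel remixing; a general invertible channel map rescales the two class
covariances unequally after normalization, which shifts eigenvalues while
leaving the filter directions intact. The invariance tests use orthogonal
mixers for this reason.

## Classifiers

* **LDA** — closed form, equal priors, no shrinkage: w = Σ⁻¹(μ₁−μ₀) with the
  biased pooled within-class covariance (divisor n, a sufficient statistic,
  so duplicating the training set leaves the model unchanged); the bias puts
  the boundary at the midpoint of the projected class means.
* **SVM** — linear kernel, C = 1.0, unpenalized intercept, solved by
  scikit-learn's SVC at tolerance 1e-6; the primal hinge objective is
  validated against a dense slack-variable QP solved with SLSQP.
* **MLP** — one hidden layer of 10 ReLU units, sigmoid output,
  cross-entropy loss, plain SGD (no momentum, no weight decay), learning
  rate 0.01, full batch, 200 epochs, seeded initialization. Loss, optimizer,
  epoch count and batch size are free choices here (only the architecture,
  activation and learning rate are fixed by the study design); all live in
  `TrainConfig`.

SVM and MLP features are z-scored on the training portion only (optimizer
conditioning); the affine standardization is folded back into the returned
model parameters so persisted models act on raw features. LDA is
affine-invariant and consumes raw features. Ties on the decision boundary
go to the positive class. Equal priors are assumed throughout — the
synthetic sessions are balanced by construction.

## Evaluation

Splits are stratified and seeded: 70/30 holdout (28/12 of 40 trials) and
5-fold CV with fold sizes differing by at most one. Within every training
portion the whole chain — class covariances, CSP filters, feature scaler,
classifier — is refitted from scratch; the label-shuffle test doubles as a
leakage detector, since any leak would lift shuffled accuracy above chance.
CV reports fold-mean metrics; the holdout regime reports test-portion
metrics plus train-portion metrics (the "training accuracy" curves).
Windows sharing a duration (the four 0.5-s and two 1-s windows) are
evaluated independently and summarized by their mean. The positive class
for the false-positive ratio is "mi" in imagery-vs-rest mode and the
right hand (configurable) in left-vs-right mode.

The full sweep is subjects × classifiers × windows × regimes
(6 × 3 × 8 × 2 = 288 cells by default). Failing cells are recorded with
their error and the sweep continues.

## Problem sizes and determinism

The trend experiments use the default cohort (6 subjects, 35 trials per
class) replicated over 20 seeds in the test suite and 5 seeds in the
acceptance script — enough replication that the per-duration means are
stable to ~1 accuracy point while a full run stays in the minutes range on
one CPU. All randomness flows from explicit integer seeds (subject seeds
are derived from the global seed); two runs with identical configuration
produce byte-identical result files.

## Known limitations

* The generator's stationary sources make the 4-s window strictly optimal
  for accuracy; real imagery has phase-dependent spatial patterns that can
  favour shorter windows — the package measures the variance mechanism
  only.
* Covariance estimation is unregularized (11 channels, ≥128 samples per
  window keeps it well-conditioned); high-density montages would need
  shrinkage, which is deliberately out of scope.
* Two-class problems only; no multiclass CSP, no filter-bank variants, no
  online/asynchronous streaming evaluation, no significance testing across
  subjects.
* Session export uses a documented `.npz` container; EDF export and GDF
  import are interoperability extras, the latter requiring `mne`.
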