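# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `oscillofuse`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The synthetic session

The generator emulates a two-choice gambling task recorded with
simultaneous EEG–fMRI. Defaults follow the paradigm the package is built
around: 4 blocks × 100 trials, TR = 2 s with 530 volumes per block,
EEG at 5000 Hz. A trial occupies a 10 s pitch — choice stimulus at 0 s
(1 s response window), selection shown in bold at +2 s, feedback at
+4 s, account balance at +6 s for 2 s, then 2 s fixation. The task
protocol does not state onset jitter, so the pitch is fixed by default
with optional uniform jitter (`onset_jitter`). Valence is a fair coin;
the stake (25 vs 5) follows a configurable policy — `fair-coin`
(default), or `always-25`/`always-5`, which reproduce the degenerate
single-stake sessions that turn condition regressors into null columns.

**EEG model.** Each feedback event adds two Gaussian-windowed sinusoidal
bursts at electrode sites with a fixed scalp topography: theta
(5.1 Hz) and high-beta (25.5 Hz), envelope s.d. 100 ms, centered 300 ms
after feedback so the envelope peak falls inside the peak-marking
windows. Per-trial amplitudes are Normal(condition mean, `trial_amp_sd`)
truncated at zero; the condition means encode the valence effects (theta
base 3 µV + 1.5 µV after losses; beta base 2 µV + 1 µV after gains;
s.d. 0.75 µV — amplitudes chosen at the few-microvolt scale of
event-related frontal oscillations, with effects large relative to the
trial s.d. so that desk-scale groups have measurable power). The burst
topography sums to zero across the eight EEG channels, as a dipolar
field does, so common-average re-referencing leaves the waveform at Fz
intact. The background is 1/f ("pink") noise, RMS 2 µV per channel. The
ECG channel carries synthetic ~60 bpm beats. Optional artifacts:

* *gradient*: a deterministic template of slice-frequency harmonics,
  repeated exactly every TR (amplitude 300 µV, volume markers emitted);
* *cardioballistic*: a smooth 0.7 s template per EEG channel (~25 µV),
  inserted 210 ms after each R wave with ±20 ms Gaussian timing jitter.

**BOLD model.** Voxel signal = Σ_c β_c·(HRF ∗ onset train of condition
c) + γθ·(HRF ∗ feedback train weighted by mean-centered true theta
power) + γβ·(same for beta) + per-voxel linear drift + AR(1) Gaussian
noise (coefficient 0.3, marginal s.d. 1 — the simplest noise model that
makes prewhitening testable). "Power" is the squared burst amplitude,
the latent counterpart of what the pipeline measures, and it is centered
within block × condition exactly as the estimation side orthogonalizes
its modulators, so the coupling coefficient is identifiable. Three
disjoint cuboid clusters on the default 12×12×12 grid (3 mm isotropic)
carry condition responses, theta coupling, and beta coupling; all other
voxels have γ = 0 exactly. Coupling strength varies across subjects by a
multiplicative factor (s.d. 0.3, clipped at 0.1) — the quantity trait
scores correlate with. By default the theta coupling is expressed on
loss trials and the beta coupling on gain trials, mirroring the
valence-specific couplings this analysis is designed to detect and
giving the loss>gain / gain>loss group contrasts a defined target;
setting `coupling_*_conditions` to all four conditions yields
valence-unspecific coupling (used by the unbiasedness tests). The first
volumes are *not* pre-discarded — discarding is the pipeline's job.

EEG bursts and BOLD coupling draw from a single set of per-trial
amplitudes stored in `GroundTruth`; one seed fixes all randomness
end-to-end through named child streams (CRC-based, process-independent).

**What the simulator does not emulate.** No eye blinks, EMG, head
motion (motion *parameters* are supplied as random walks, but the data
never move), no spatial autocorrelation of BOLD noise, no slice timing
or registration errors (data are generated aligned), no non-stationary
artifact templates. Passing tests therefore certify the numerical
pipeline, not robustness to every failure mode of real recordings.

## EEG cleanup

* Gradient artifact: for each volume epoch, the mean of the surrounding
  2·15+1 epochs (each corrected by its own mean) is subtracted;
  one-sided windows at the edges; drifting inter-volume intervals (> 1
  sample) raise an alignment error rather than smearing the template.
* Cardioballistic artifact: R peaks are detected fully automatically —
  high-prominence candidates seed a beat template, normalized
  cross-correlation re-detects beats with a 180 bpm refractory bound.
  Each beat's artifact latency is then refined (±40 ms) against the
  grand template before the sliding-average (2·10+1 beats) subtraction;
  without the refinement, physiological latency jitter caps cancellation
  well below its potential. Channels whose pulse-locked template does
  not exceed 4× the averaging noise floor are left untouched, so clean
  recordings pass through essentially unchanged.
* Filtering: zero-phase (forward–backward) Butterworth; the stated
  single-pass design slopes are 12 dB/oct (order 2) for the 50 Hz
  low-pass and 48 dB/oct (order 8) for the 0.1 Hz high-pass. Two-pass
  filtering squares the magnitude response: at the 25.5 Hz layer the
  designed power gain is |H|⁴ ≈ 0.877, a known, deterministic
  attenuation that the neutrality test accounts for explicitly; the
  5.1 Hz layer sits far from both edges and is neutral to < 5 %.
* Epochs: [−1800, +1200) ms at 500 Hz (1500 samples), baseline
  [−200, 0) ms, half-open intervals everywhere. "Voltage step" is
  operationalized as the consecutive-sample difference and "activity
  below 0.5 µV" as peak-to-peak range over the whole epoch; both
  readings of the screening rules are ambiguous in prose, and the
  chosen operationalizations are recorded per trial with the rejection
  reasons. Criteria apply to all EEG channels (not only channels of
  interest) — the stricter reading.

## Time–frequency analysis

Layer centers f_k = 2·25^(k/24) Hz, k = 0…24; a layer's band edges are
its neighbours' centers. Displayed values are *truncated* (not rounded)
to one decimal, which reproduces the conventional display values 5.1,
25.5, 4.4 and 5.8. The Morlet wavelet has c = 6 cycles
(σ_t = c/2πf), support truncated at ±5σ_t, unit-energy envelope, and is
amplitude-calibrated at the layer center so that a sinusoid of amplitude
A yields plateau power A² — without calibration a unit-energy wavelet's
passband gain is arbitrary and power would not be comparable to an
envelope-squared oracle. The 1800 ms pre-stimulus segment keeps the
analysis windows outside the edge cone at 5.1 Hz.

The baseline norm *n* is the **mean** power over the baseline samples
(sum ÷ count): a stationary signal then normalizes to 1. The
alternative reading — baseline sum weighted by the baseline/segment
length ratio — is available via `weighted_sum=True`. Trials with
*n* ≤ 1e−12 are flagged invalid and excluded downstream rather than
silently becoming NaN.

A consequence worth stating plainly: at a layer ~1.4 Hz wide, the
200 ms baseline contains roughly *one* independent complex sample, so
per-trial *n* is close to a χ²₂ draw and per-trial normalized power is
heavy-tailed. This is intrinsic to per-trial baseline normalization at
low frequencies, not a bug; it attenuates single-trial EEG–BOLD
modulators by a subject-varying factor and is the main reason coupling
detection through the *measured* (rather than latent) modulator needs
either large groups or lenient voxel thresholds (see Limitations).

**Mixed model.** Subject × condition mean peaks are fit by
`mean ~ valence + magnitude` (effect-coded, interaction optional and off
by default) with a random subject intercept and condition-specific
residual variances — a 4×4 compound-symmetry-plus-diagonal covariance
per subject. Variance components are estimated by **REML** (default):
plain ML (available via `method="ml"`) biases the variance components
low with ~19 subjects and makes the Wald tests measurably liberal
(empirical level ≈ 0.055 at nominal 0.05), which REML corrects. Fixed
effects are tested with Wald F (1 numerator df); the denominator df use
a Satterthwaite approximation via the delta method, with the variance
parameter covariance taken from the numerical Hessian of the profiled
criterion. Balanced designs share one per-subject covariance and take a
fast vectorized path; unbalanced designs fall back to per-subject
Cholesky factors. Singular fits return `converged=False` instead of
raising.

## EEG-informed GLM

The canonical HRF is the standard double gamma (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot 6, 32 s
support), peak-normalized, sampled on a microtime grid of TR/16; event
trains are binned on that grid, convolved, and linearly interpolated at
the frame times. All regressors model events as impulses (duration 0) —
stage durations are bounded by the task script but the modeling choice
is not dictated by it, and impulses are the simplest defensible option,
including for the anticipation phase.

Parametric modulators are single-trial peak powers minus their
block × condition cell mean; cell means of the weights are zero to
machine precision, which keeps each modulator empirically near-orthogonal
to its own onset regressor. A condition absent from the whole session
raises a null-regressor error naming the condition; a modulator that is
identically zero (every cell of that condition had ≤ 1 trial) is dropped
from the design rather than left as a rank-breaking null column, and
the pipeline records the substitution.

First-level fitting is voxelwise least squares (pseudo-inverse), with
optional two-pass AR(1) prewhitening: pooled lag-1 residual
autocorrelation, within-block quasi-differencing (first frame scaled by
√(1−φ²)), refit. Smoothing, when requested, is a separable Gaussian
with FWHM in mm converted through the voxel size. Rank-deficient
designs raise an error listing the collinear columns.

The second-level factorial (valence × magnitude × subject-as-random) is
implemented as the partitioned-error within-subject contrast: each
single-df contrast is evaluated per subject and tested against zero
across subjects. For a two-condition contrast this is *exactly* a
paired t-test (the correctness anchor, asserted to 1e−8); SPM-style
covariance-component machinery is deliberately out of scope. Cluster
inference thresholds the one-sided t map (26-connectivity, SPM
convention), drops clusters below the extent threshold, and computes
cluster p-values from a sign-flip permutation null of the maximum
supra-threshold cluster size (default 1000 permutations, seeded) —
permutation replaces random-field theory, is exact under the
sign-symmetry of the null, and is the package's deliberate deviation
from parametric cluster p-values. Surviving clusters are BH-FDR
corrected.

## ROI statistics

Sphere membership is by Euclidean distance of the voxel *center* from
the ROI center in mm (no partial-volume weighting — the simplest
reproducible rule). The ROI summary is the mean coefficient over member
voxels per subject. Pearson p-values come from
t = r·√(n−2)/√(1−r²) with n−2 df, two-tailed. The BH step-up family
size *m* defaults to (ROIs × subscales) but may be set larger when the
family includes examined-but-unreported members; *m* is always recorded
in the output. Correlations are reported signed, as computed —
interpretation of sign conventions is left to the user.

## Problem sizes used by tests and the acceptance script

Desk-scale simulations keep everything inside seconds-to-minutes on one
CPU: typically 1–12 subjects, 1–2 blocks × 20–40 trials, 500 Hz EEG,
6³–10³ voxel grids, 110–210 volumes per block, 30–200 permutations, and
Monte-Carlo loops of 50 (coupling recovery), 150–500 (mixed-model error
rates, voxelwise calibration) replicates. The full 4 × 100-trial,
530-volume configuration remains the generator default and is exercised
directly in the end-to-end heavy-tail analysis referenced under
Limitations.

## Known limitations

* Per-trial baseline normalization makes single-trial low-frequency
  power heavy-tailed (χ²₂-like baseline, see above). With the
  *measured* modulator, group t-values over coupled voxels saturate
  around ~2.3 at desk scale almost independently of trial count; the
  end-to-end test therefore demonstrates sensitivity > 0.8 at a
  one-sided voxel p < 0.05 with a nominal false-positive rate, while
  stricter thresholds require group sizes beyond a desk-scale run.
  Recovery of γ from the latent (true-power) modulator is unbiased.
* The AR(1) prewhitening uses one pooled coefficient; voxelwise AR
  models beyond lag 1 are out of scope.
* Cluster-level inference assumes sign-symmetric exchangeability across
  subjects; no spatial autocorrelation is modeled in the simulator, so
  permutation null distributions on real, smoothed data will differ.
* The EDF writer quantizes to 16 bits over the observed per-channel
  range; recordings with extreme outliers lose amplitude resolution.
* ICA-based artifact removal, visual inspection steps, slice timing,
  realignment and template registration are intentionally absent.
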