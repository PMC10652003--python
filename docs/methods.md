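# Methods

This note documents the models, estimators, parameter choices, and known
limitations of `pullkin`, in the order the pipeline runs.

## Coordinate conventions and input quality control

Pose tables arrive in image coordinates (y grows downward). The loader flips
y to up-positive (`frame_height − y`) so that a *reach* is a rising excursion
and a *pull* a falling one; every downstream semantic (peak = reach-to-pull
transition, negative velocity = downward pulling motion) assumes this.
Frames are 0-based; time is `frame / fps` seconds. The frame rate is treated
strictly as input metadata; examples default to 59.94 Hz, the common NTSC
camera rate. (Source material for this pipeline quotes both 59.64 and
59.94 fps in different places; 59.94 is used here as the physically standard
value.)

Label-jump flagging marks every frame whose Euclidean displacement from the
previous labeled point is at least a threshold — 10 px for the rodent
dialect, 20 px for the human dialect, both overridable. The criterion is
inclusive at the threshold. The per-frame likelihood column, when present,
is carried through for provenance but never used to filter: cleaning is done
kinematically (below), not by confidence gating.

## Filtering

All filters are Butterworth designs applied forward-backward
(`scipy.signal.sosfiltfilt`), so the pass is zero-phase: peak timing and
FWHM are not biased by filter lag. The cost is that the effective magnitude
response is the *square* of the single-pass response — e.g. the rodent
cascade passes a 2 Hz pulling carrier at gain ≈ 0.88, not 1.0. Tests
therefore compare measured amplitudes against the analytic zero-phase
cascade response (`preset_gain`), never against unity; ratio-type biomarkers
(symmetry ratios, dynamic-range ratio) are unaffected because both operands
see the same cascade.

Presets:

| preset | stages | used for |
|---|---|---|
| `rodent_full` | HP 0.75 Hz order 1 → LP 9 Hz order 3 | all rodent analyses |
| `human_peaks` | HP 0.1 Hz order 1 → LP 7 Hz order 7 | human peak/trough detection |
| `human_lowpass_only` | LP 7 Hz order 7 | human waveform shape, synergies, dynamic range |

Edge handling is odd-reflection padding of length `3·max(3·order, 12)`
samples (capped at signal length − 1). Short clips (~15 s) make edge
transients non-negligible; this padding keeps them out of the analyzed span.
Filters are designed per recording from its fps; no normalized frequencies
are hard-coded.

## Epoch segmentation

Peaks and troughs are detected on the filtered vertical trace with
`scipy.signal.find_peaks` applied to the trace and its negation, with two
scale-free defaults (both config-exposed):

- prominence floor = 25% of the robust amplitude (half the 5th–95th
  percentile range of the filtered trace), which survives occlusion jitter
  without per-recording tuning;
- minimum same-kind separation = 0.1 s.

The merged candidate sequence is repaired to strict alternation: within a
same-kind run the more extreme candidate wins, ties keep the earlier one.
Epochs are emitted only between consecutive extrema (partial leading and
trailing phases are discarded), so reach and pull counts differ by at most
one and epoch durations tile the extremum span exactly. Amplitudes are
reported in raw pixels; cross-subject comparability therefore assumes a
standardized camera geometry.

## Waveform shape (FWHM, velocity, acceleration)

The mean-centered vertical trace is cut at its negative-to-positive and
positive-to-negative zero crossings, located to sub-frame precision by
linear interpolation between the two bracketing samples. Each positive
excursion with ≥ 4 interior samples becomes a segment, resampled to 100
evaluation points by an *interpolating* (smoothing factor 0) 2nd-degree
spline with knots at the data — deterministic and oracle-checkable. The
"100 points" are evaluation points, not knots.

FWHM is the width at half the segment maximum (the baseline is the zero
line by construction), measured from the first up-crossing to the last
down-crossing of the half level — the last-crossing convention makes the
measure well-defined for multimodal segments. The grid width maps back to
fractional video frames through the segment's true duration. Closed-form
checks: a half-sine of period T has FWHM = T/3 (sine crosses half-max at
T/12 and 5T/12); a symmetric triangle peak has FWHM of half its base.

Velocity and acceleration are central differences on the 100-point grid
(one-sided at the endpoints), rescaled by the chain rule
d/dt = (99/duration)·d/d(index) so units are px/s and px/s². Velocity is
signed; pooled distributions concatenate all interpolated samples across a
recording's segments, arms kept separate.

## Kinematic synergies

The filtered, mean-centered channels are stacked as T ∈ ℝ^(c×t) (rodent:
R_X, R_Y, L_X, L_Y; human adds the four elbow channels) and decomposed with
an economy SVD in the channels × frames orientation, one decomposition per
recording (no concatenation across sessions). Variance explained per
component is sᵢ²/Σⱼsⱼ². Because a singular-vector pair's sign is arbitrary,
each weight column is flipped so its largest-magnitude entry is positive —
presentation only, since downstream analyses use |U[channel, component]|.
Human synergy matrices use the low-pass-only preset (human traces carry
little drift); rodent matrices use the full cascade.

## Bicoherence

Cross-frequency coupling between the PC1 and PC2 temporal modes is
estimated as a normalized cross-bicoherence over spectrogram windows
(Hann taper, mean-detrended, 2 s windows, 1 s overlap):

    b(f1, f2) = |Σₖ X₁ₖ(f1)·X₂ₖ(f2)·conj(X₂ₖ(f1+f2))|
                / √( Σₖ|X₁ₖ(f1)·X₂ₖ(f2)|² · Σₖ|X₂ₖ(f1+f2)|² )

with the sum-frequency term drawn from mode 2 and f1+f2 capped at Nyquist.
Cauchy–Schwarz bounds the magnitude in [0, 1]; magnitude (not squared)
coherence is reported. A direct-summation oracle (manual windowed FFTs) pins
this definition in the tests. Numerical note: bins with essentially zero
power (e.g. the detrended DC row) hold cancellation noise whose ratio is not
meaningful; statements about the map should be restricted to bins with
genuine power. Under the null, each value's square is ~Beta(1, n_windows−1),
which gives analytic bounds for band maxima.

Maps are computed on the native spectrogram grid (df = 1/window_s) and
bilinearly interpolated onto a fixed 0–15 Hz grid in 0.1 Hz steps so that
recordings of different lengths can be averaged arithmetically. Band
summaries default to the maximum over nodes with *both* axes inside the band
(a sum-frequency-in-band convention is available by flag).

## Bilateral statistics

Hand-movement consistency is the Pearson correlation of the filtered
right-vs-left x and y traces within a recording. Note that band-limiting
shrinks the effective sample size to roughly 2·bandwidth·duration, so null
correlations of independent traces are wider than the 1/√n intuition — the
tests bound them with that effective-n oracle.

The dynamic-range ratio is std(hand_y)/std(elbow_y) on low-pass-filtered,
mean-centered vertical traces, per side (human dialect only; rodent elbows
are not tracked). Distribution summaries use quartiles by linear
interpolation of order statistics (the numpy default), IQR = Q3 − Q1
exactly, and SEM with the n−1 denominator; the quartile convention is
config-switchable.

## Biomarker vector and classifier

Per arm: mean reach/pull time, mean reach/pull amplitude, mean FWHM, mean
signed velocity. Pair level: right:left symmetry ratios of reach/pull
amplitude and time. Human recordings add the per-arm dynamic-range ratio
(the per-arm reading of an ambiguous convention; a single pooled ratio is
available by flag). A recording with no detectable epochs on an arm is
excluded with a logged reason.

The classifier is L2-penalized logistic regression, C = 0.001, saga solver,
under stratified 3-fold cross-validation. Features are z-scored with
statistics fit on each training fold: a penalty that strong is meaningless
across mixed units (pixels vs seconds) without scaling. Folds are grouped
by subject by default so one participant's trials never straddle the
train/test split (toggle off for exact ungrouped stratification). The mean
ROC is a vertical average of per-fold curves on a fixed 101-point FPR grid
with a ±1 sd band; sensitivity/specificity are taken at the 0.5 probability
threshold (the ROC-optimal point is not used). AUC is reported as mean ± sd
across folds.

## Synthetic trajectory generator

The generator emulates the phenomenology the pipeline is built to measure;
defaults describe a healthy adult-scale recording (59.94 fps, 15 s, 2 Hz
pulling cycle, 50 px vertical half-range):

- **Vertical waveform**: piecewise-sinusoidal cycle rising over
  `rise_fraction` (default 0.35 — reaches evolve faster than pulls) and
  falling over the remainder, arms offset by `phase_offset` (default π,
  anti-phase).
- **Injury phenotype** (applied to `injured_arm` only): `amplitude_scale_injured`
  (default tear value 0.6) multiplies the arm's excursion;
  `pull_slope_scale` (tear 0.5) blends the sinusoidal fall toward a
  constant-velocity ramp — same endpoints and duration, so epoch amplitudes
  are untouched while peak downward velocity drops (up to a 2/π factor),
  thinning the negative-velocity tail; `elbow_ratio_injured` (human tear
  0.4) slackens the elbow and raises the dynamic-range ratio.
- **Peak rounding** (`peak_rounding_s`, healthy 0.02 s, tear 0.04 s):
  a Gaussian-smoothed copy of the trace is blended in with weight
  clip(y/A, 0, 1)², i.e. only near the waveform tops. This broadens FWHM
  monotonically with the rounding width while leaving troughs and the
  overall excursion essentially intact — whole-trace smoothing would
  attenuate the 2 Hz fundamental itself and confound the amplitude
  biomarkers.
- **Noise**: shared low-frequency lateral sway (coupling gain drives the
  between-arm x correlation), shared sinusoidal postural drift (8 px at
  0.1 Hz), white labeling jitter (1 px), and occlusion bursts — 0.25–0.5 s
  episodes whose displacement sign alternates every 2 frames (≈15 Hz at
  60 fps) under a Hann amplitude envelope, emulating tracking-confidence
  breakdown during brief occlusions. The alternation frequency sits above
  the rodent 9 Hz low-pass cutoff by construction, so the preset suppresses
  bursts (> 90% peak attenuation) while passing the pulling carrier; the
  ramped envelope reflects gradual label degradation and keeps the burst
  energy concentrated at the alternation frequency rather than in onset
  steps.
- **Determinism**: one seeded generator per recording with a fixed draw
  order (drift phase, shared sway, then per-track noise in channel order),
  so a seed always reproduces a bit-identical recording and adding a new
  optional noise source can be appended without perturbing earlier draws.

`generate_cohort` jitters each subject's base frequency and amplitude by a
seeded log-normal factor (CV 0.1) so within-subject trials correlate more
than across subjects; a "null tear" phenotype (tear label, healthy
kinematics) supports chance-level classifier checks.

What the generator does *not* emulate: biomechanically realistic joint
kinematics, body-size/pixel-scale variation between subjects, camera
perspective effects, missing frames, or genuinely non-stationary pulling
rhythm. Passing tests therefore demonstrate correctness of the measurement
pipeline under the modeled phenomenology, not clinical performance on real
recordings.

## Numerical choices and degenerate inputs

- Zero crossings that coincide with a sample to float precision are merged
  into the crossing knot before spline fitting (strictly increasing knots).
- Bicoherence values are clipped to [0, 1] against float overshoot of the
  Cauchy–Schwarz bound; zero-denominator bins report 0.
- Zero-variance traces (correlation, dynamic range), immobile elbows,
  single-class tables, and non-finite features raise typed errors naming
  the offending quantity rather than propagating NaNs.
- Constant trajectories yield no extrema and no segments (empty results,
  not errors); a rank-deficient kinematic matrix is allowed (zero singular
  values), but an all-zero matrix is rejected.

## Problem sizes used in tests and the acceptance script

Analytic oracles run on seconds-long synthetic signals; parameter-recovery
and classifier checks use 15 s recordings, cohorts of 6 + 6 subjects with 2
trials each, and 10-seed repetitions. These sizes give stable Monte-Carlo
estimates (null-AUC sd across seeds ≈ 0.06) while keeping the full suite
and the acceptance script fast to run routinely.

## Known limitations

- Pixel-unit amplitudes are camera-geometry dependent; no size normalization
  is applied.
- The bicoherence estimator is one member of a family of normalizations;
  alternative normalizations rescale maps and thresholds.
- Sensitivity/specificity at the fixed 0.5 threshold can understate
  performance for imbalanced cohorts.
- The CLI's `extract` emits the synergy and bicoherence stage outputs
  directly (synergy.json, bicoherence.csv) rather than via separate
  subcommands; stages remain individually testable through the library API.
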