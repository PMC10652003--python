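# pullkin

Kinematic assessment of shoulder function from markerless motion capture of
**string-pulling behavior** — the bimanual, hand-over-hand rope-pulling task
whose anti-phase oscillatory hand trajectories are conserved from rodents to
humans. Rotator-cuff (RC) tears degrade these trajectories in characteristic
ways: reduced movement amplitude, prolonged movement time, blunted pull
velocity, a rounded reach-to-pull transition, and (in humans) compensation of
a stiff shoulder by humeral rotation. `pullkin` turns pose-estimation output
(per-frame x/y hand — and, for humans, elbow — coordinates) into these
biomarkers and into a cross-validated injury classifier.

Intended users: motor-behavior and musculoskeletal-injury researchers who
already run markerless pose estimation (e.g. DeepLabCut-style CSV output) and
need the downstream analysis: filtering, segmentation, waveform shape,
synergies, coupling, and classification.

## What it computes

- **Preprocessing** — zero-phase Butterworth cascades. Rodent: 0.75 Hz
  1st-order high-pass (postural drift) + 9 Hz 3rd-order low-pass (labeling
  jitter). Human: 0.1 Hz high-pass + 7 Hz 7th-order low-pass for peak
  detection; low-pass only for waveform shape and synergies.
- **Reach/pull epochs** — alternating peaks/troughs of the vertical hand
  trajectory; a *reach* is each trough→peak interval, a *pull* each
  peak→trough interval, with amplitude (px) and duration (s).
- **Waveform shape** — each positive excursion of the mean-centered vertical
  trace (between its zero crossings) is resampled to 100 points with an
  interpolating 2nd-degree spline; the **FWHM** (width of the peak at half
  its maximum, in fractional video frames) is a fluency index of the
  reach-to-pull transition, and first/second derivatives give velocity
  (px/s) and acceleration (px/s²).
- **Kinematic synergies** — the filtered, mean-centered coordinate channels
  form T ∈ ℝ^(c×t) (rodent: R_X, R_Y, L_X, L_Y; human: 8 hand+elbow
  channels), decomposed as T = U·S·Vᵀ. Columns of U are synergies, squared
  singular values give variance explained (sᵢ²/Σs²), rows of Vᵀ are temporal
  modes.
- **Bicoherence** — normalized cross-bispectral coupling b(f1, f2) ∈ [0, 1]
  between the PC1 and PC2 temporal modes over 2 s spectrogram windows with
  1 s overlap, interpolated onto a fixed 0–15 Hz grid (0.1 Hz steps), with
  band maxima (e.g. 2–4 Hz) as summaries.
- **Bilateral statistics** — Pearson correlations of right-vs-left filtered
  traces; right:left symmetry ratios of epoch means; the movement **dynamic
  range ratio** std(hand_y)/std(elbow_y), ≈1 for shoulder-pivot motion and
  ≫1 for humeral-rotation compensation.
- **Classifier** — L2-regularized logistic regression (C = 0.001, saga
  solver) on the per-recording biomarker vector, evaluated with stratified
  3-fold cross-validation (subject-grouped folds by default), reporting the
  mean ROC, AUC ± sd, sensitivity and specificity.

A fully parameterized synthetic-trajectory generator (anti-phase
oscillations with faster rise than fall, lateral sway coupling, postural
drift, labeling jitter, occlusion bursts, and configurable injury
phenotypes) makes every stage testable without animal or patient data.

## Worked example

```python
from pullkin import (assemble_features, build_matrix, decompose,
                     cumulative_variance, abs_weights, generate_recording)
from pullkin.simulate import tear_params

rec, truth = generate_recording(tear_params("human", seed=7), subject_id="P01")
fv = assemble_features(rec)
print(f"recording: {fv.recording_id}  label: {fv.label}")
for k in ("right_mean_reach_amplitude_px", "left_mean_reach_amplitude_px",
          "reach_amplitude_ratio", "right_mean_fwhm_frames",
          "right_dynamic_range_ratio", "left_dynamic_range_ratio"):
    print(f"  {k:32s} {fv.features[k]:8.3f}")
d = decompose(build_matrix(rec))
print(f"  PC1+PC2 variance explained       {cumulative_variance(d, 2):8.3f}")
w = abs_weights(d, 0, ("R_Y", "L_Y"))
print(f"  |PC1 weight| R_Y vs L_Y          {w['R_Y']:.3f} vs {w['L_Y']:.3f}")
```

prints:

```
recording: P01/sim  label: tear
  right_mean_reach_amplitude_px      54.686
  left_mean_reach_amplitude_px       94.556
  reach_amplitude_ratio               0.578
  right_mean_fwhm_frames             10.235
  right_dynamic_range_ratio           2.098
  left_dynamic_range_ratio            1.000
  PC1+PC2 variance explained          0.949
  |PC1 weight| R_Y vs L_Y          0.339 vs 0.659
```

The injured (right) arm reaches with ~58% of the healthy arm's amplitude
(the generator injected a 0.6 amplitude scale), its dynamic range ratio of
2.1 flags humeral-rotation compensation (elbow moving much less than the
hand), two synergies carry ~95% of the kinematic variance, and the PC1
weight magnitude has diverged between the injured and uninjured hands.

### Command line

```bash
pullkin simulate --preset human --phenotype healthy --n 3 --seed 1 --out data/
pullkin simulate --preset human --phenotype tear    --n 3 --seed 1 --out data/
pullkin extract  --input data/ --out results/ --seed 1
pullkin classify --features results/features.csv --c 0.001 --folds 3 --seed 1
pullkin report   --out results/
```

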