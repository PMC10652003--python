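import numpy as np
import pytest

from pullkin.errors import ParameterError
from pullkin.preprocess import apply_preset, mean_center
from pullkin.segmentation import detect_extrema, extract_epochs
from pullkin.simulate import (
    PhenotypeParams,
    generate_cohort,
    generate_recording,
    healthy_params,
    tear_params,
)
from pullkin.waveform import compute_fwhm, extract_peak_segments, pooled_velocity


def _epoch_amplitudes(rec, side, filtered=False):
    y = rec.tracks[f"{side}_hand"].y
    if filtered:
        y = apply_preset(y, rec.fps, "rodent_full")
    epochs = extract_epochs(detect_extrema(y - y.mean(), rec.fps), rec.fps)
    return [e.amplitude for e in epochs]


class TestGenerateRecording:
    def test_same_seed_bit_identical(self):
        p = healthy_params("human", seed=42)
        r1, _ = generate_recording(p)
        r2, _ = generate_recording(p)
        for label in r1.tracks:
            np.testing.assert_array_equal(r1.tracks[label].x, r2.tracks[label].x)
            np.testing.assert_array_equal(r1.tracks[label].y, r2.tracks[label].y)

    def test_different_seed_differs(self):
        r1, _ = generate_recording(healthy_params("rodent", seed=1))
        r2, _ = generate_recording(healthy_params("rodent", seed=2))
        assert not np.array_equal(r1.tracks["right_hand"].y, r2.tracks["right_hand"].y)

    def test_zero_noise_epoch_amplitudes_match_construction(self):
        p = healthy_params(
            "rodent", jitter_px=1e-12, occlusion_rate=0.0, drift_px=1e-12,
            peak_rounding_s=0.0, seed=5,
        )
        rec, truth = generate_recording(p)
        amps = _epoch_amplitudes(rec, "right")
        assert np.mean(amps) == pytest.approx(truth.amplitude_px["right"], rel=0.01)
        assert truth.amplitude_px["right"] == 2 * p.amplitude_px

    def test_injured_amplitude_ratio(self):
        p = tear_params("rodent", amplitude_scale_injured=0.6, pull_slope_scale=1.0,
                        peak_rounding_s=0.02, seed=6)
        rec, _ = generate_recording(p)
        ratio = np.mean(_epoch_amplitudes(rec, "right", filtered=True)) / np.mean(
            _epoch_amplitudes(rec, "left", filtered=True)
        )
        assert ratio == pytest.approx(0.6, rel=0.05)

    def test_ground_truth_landmarks_match_trace(self):
        p = healthy_params("rodent", jitter_px=1e-12, occlusion_rate=0.0,
                           drift_px=1e-12, peak_rounding_s=0.0, seed=7)
        rec, truth = generate_recording(p)
        y = rec.tracks["right_hand"].y
        for f in truth.peak_frames["right"][1:-1]:
            window = y[max(0, f - 3) : f + 4]
            assert y[f] == pytest.approx(window.max(), abs=0.02 * p.amplitude_px)

    def test_parameter_validation_lists_fields(self):
        with pytest.raises(ParameterError, match="rise_fraction"):
            PhenotypeParams(rise_fraction=1.5)
        with pytest.raises(ParameterError, match="cycle_hz"):
            PhenotypeParams(cycle_hz=-1)

    def test_human_dialect_has_elbows(self):
        rec, _ = generate_recording(healthy_params("human", seed=8))
        assert set(rec.tracks) == {"right_hand", "left_hand", "right_elbow", "left_elbow"}


class TestPhenotypeEffects:
    def test_fwhm_monotone_in_peak_rounding(self):
        medians = []
        for rounding in (0.0, 0.0125, 0.025, 0.0375, 0.05):
            rec, _ = generate_recording(
                healthy_params("rodent", peak_rounding_s=rounding, seed=5)
            )
            y = mean_center(apply_preset(rec.tracks["right_hand"].y, rec.fps, "rodent_full"))
            widths = [compute_fwhm(s, rec.fps) for s in extract_peak_segments(y, rec.fps)]
            medians.append(np.median(widths))
        assert np.all(np.diff(medians) > 0)

    def test_blunted_pull_reduces_negative_velocity_tail(self):
        def pooled(params_fn, seeds):
            out = []
            for s in seeds:
                rec, _ = generate_recording(params_fn(s))
                y = mean_center(apply_preset(rec.tracks["right_hand"].y, rec.fps, "rodent_full"))
                out.append(pooled_velocity(extract_peak_segments(y, rec.fps), rec.fps))
            return np.concatenate(out)

        v_healthy = pooled(lambda s: healthy_params("rodent", seed=100 + s), range(5))
        v_tear = pooled(lambda s: tear_params("rodent", seed=s), range(5))
        threshold = np.percentile(v_healthy, 10)  # large-magnitude downward motion
        assert np.mean(v_tear < threshold) < np.mean(v_healthy < threshold)

    def test_lateral_coupling_strengthens_x_correlation(self):
        from pullkin.bilateral import hand_correlations

        r_values = []
        for coupling in (0.1, 0.5, 1.0, 2.0):
            rec, _ = generate_recording(
                healthy_params("rodent", lateral_coupling=coupling, seed=7)
            )
            r_values.append(hand_correlations(rec)[0])
        assert np.all(np.diff(r_values) > 0)

    def test_y_correlation_follows_phase_offset(self):
        # identical arms (offset 0) are perfectly correlated; anti-phase arms
        # strongly anti-correlated (not exactly -1: the waveform is asymmetric)
        r_by_offset = {}
        for offset in (0.0, np.pi / 2, np.pi):
            from pullkin.bilateral import hand_correlations

            p = healthy_params("rodent", phase_offset=offset, jitter_px=1e-9,
                               occlusion_rate=0.0, drift_px=1e-9, seed=9)
            rec, _ = generate_recording(p)
            r_by_offset[offset] = hand_correlations(rec)[1]
        assert r_by_offset[0.0] > 0.99
        assert r_by_offset[np.pi] < -0.85
        assert r_by_offset[0.0] > r_by_offset[np.pi / 2] > r_by_offset[np.pi]


class TestGenerateCohort:
    def test_bookkeeping(self):
        cohort = generate_cohort(6, 6, trials_per_subject=2, seed=0, species_dialect="rodent")
        assert len(cohort) == 24
        assert len(cohort.subjects()) == 12
        labels = {r.cohort for r in cohort.recordings}
        assert labels == {"control", "injured"}

    def test_same_seed_bit_identical_cohort(self):
        c1 = generate_cohort(2, 2, trials_per_subject=1, seed=3, species_dialect="rodent")
        c2 = generate_cohort(2, 2, trials_per_subject=1, seed=3, species_dialect="rodent")
        for r1, r2 in zip(c1.recordings, c2.recordings):
            np.testing.assert_array_equal(r1.tracks["right_hand"].y, r2.tracks["right_hand"].y)

    def test_within_subject_trials_more_similar_than_across(self):
        cohort = generate_cohort(4, 4, trials_per_subject=2, seed=1, species_dialect="rodent")
        from pullkin.classifier import assemble_features

        amps = {}
        for rec in cohort.recordings:
            fv = assemble_features(rec)
            amps.setdefault(rec.subject_id, []).append(fv.features["right_mean_reach_amplitude_px"])
        within = np.mean([abs(v[0] - v[1]) for v in amps.values()])
        means = [np.mean(v) for v in amps.values()]
        across = np.mean([abs(a - b) for i, a in enumerate(means) for b in means[i + 1 :]])
        assert within < across
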