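"""Synthetic string-pulling trajectory generator with ground truth.

Emulates the phenomenology of real string-pulling recordings: anti-phase
bimanual vertical oscillations with a faster rise (reach) than fall (pull),
correlated lateral sway between arms, low-frequency postural drift, white
labeling jitter, and brief high-frequency occlusion bursts.  Injury
phenotypes are expressed through an arm-specific amplitude reduction, a
blunted pull (reduced peak downward velocity at unchanged excursion), and
rounding of the waveform peak (which broadens the FWHM); human recordings add
elbow tracks whose vertical range is a configurable fraction of the hand's.

All randomness flows from a single seeded generator per recording with a
fixed draw order (drift phase, shared sway, then per-track noise in channel
order), so the same seed always yields a bit-identical recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from pullkin.errors import ParameterError
from pullkin.io import CohortTable, Recording, Track

__all__ = ["PhenotypeParams", "GroundTruth", "generate_recording", "generate_cohort", "healthy_params", "tear_params", "null_tear_params"]


@dataclass(frozen=True)
class PhenotypeParams:
    """Generator settings for one recording.

    The clean per-arm vertical waveform rises sinusoidally from trough to
    peak over ``rise_fraction`` of each cycle and falls over the remainder;
    ``pull_slope_scale`` < 1 blends the fall toward a constant-velocity ramp,
    which lowers the peak downward velocity without changing the excursion.
    ``amplitude_scale_injured``, ``pull_slope_scale`` and
    ``elbow_ratio_injured`` apply to ``injured_arm`` only; ``peak_rounding_s``
    is a subject-level waveform property applied to both arms.
    """

    fps: float = 59.94
    duration_s: float = 15.0
    cycle_hz: float = 2.0
    amplitude_px: float = 50.0
    rise_fraction: float = 0.35
    phase_offset: float = math.pi  # radians between arms (anti-phase)
    injured_arm: str = "none"  # "left" | "right" | "none"
    amplitude_scale_injured: float = 1.0
    peak_rounding_s: float = 0.02
    pull_slope_scale: float = 1.0
    compensation_gain: float = 1.0  # amplitude gain on the uninjured arm
    lateral_coupling: float = 0.6
    sway_px: float = 10.0
    indep_sway_px: float = 4.0
    elbow_ratio: float = 1.0
    elbow_ratio_injured: float | None = None
    drift_px: float = 8.0
    drift_hz: float = 0.1
    jitter_px: float = 1.0
    occlusion_rate: float = 0.1  # bursts per second
    occlusion_px: float = 30.0
    species_dialect: str = "rodent"
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not 0 < self.rise_fraction < 1:
            problems.append("rise_fraction must be in (0, 1)")
        if self.fps <= 2 * self.cycle_hz:
            problems.append("fps must exceed 2 × cycle_hz")
        for name in ("amplitude_px", "amplitude_scale_injured", "pull_slope_scale",
                     "compensation_gain", "elbow_ratio", "cycle_hz", "duration_s"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.injured_arm not in ("left", "right", "none"):
            problems.append("injured_arm must be left/right/none")
        if self.species_dialect not in ("rodent", "human"):
            problems.append("species_dialect must be rodent/human")
        if problems:
            raise ParameterError("; ".join(problems))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put in, per arm, before noise injection."""

    trough_frames: dict[str, np.ndarray]
    peak_frames: dict[str, np.ndarray]
    amplitude_px: dict[str, float]  # clean trough-to-peak excursion per arm
    rise_fraction: float
    elbow_ratio: dict[str, float]
    phenotype: str  # "healthy" | "tear"


def healthy_params(species_dialect: str = "rodent", **overrides) -> PhenotypeParams:
    """Healthy-control phenotype defaults."""
    return replace(PhenotypeParams(species_dialect=species_dialect), **overrides)


def tear_params(species_dialect: str = "rodent", injured_arm: str = "right", **overrides) -> PhenotypeParams:
    """Rotator-cuff-tear phenotype: reduced injured-arm amplitude, blunted
    pull velocity, doubled peak rounding, and (human) a lax elbow ratio."""
    base = PhenotypeParams(
        species_dialect=species_dialect,
        injured_arm=injured_arm,
        amplitude_scale_injured=0.6,
        pull_slope_scale=0.5,
        peak_rounding_s=0.04,
        elbow_ratio_injured=0.4 if species_dialect == "human" else None,
    )
    return replace(base, **overrides)


def null_tear_params(species_dialect: str = "rodent", injured_arm: str = "right", **overrides) -> PhenotypeParams:
    """A 'tear'-labeled phenotype with healthy kinematics: the injured arm is
    annotated but every injury effect is neutral.  Used for null-effect
    (label-only) cohorts when probing classifier chance performance."""
    base = PhenotypeParams(species_dialect=species_dialect, injured_arm=injured_arm)
    return replace(base, **overrides)


def _clean_arm_waveform(t: np.ndarray, p: PhenotypeParams, phase0: float, slope_scale: float) -> np.ndarray:
    """Piecewise-sinusoidal oscillation: rise over rise_fraction of the cycle,
    fall (optionally blended toward linear) over the rest.  Range [−A, A]."""
    phi = (p.cycle_hz * t + phase0 / (2 * math.pi)) % 1.0
    rf = p.rise_fraction
    y = np.empty_like(t)
    rising = phi < rf
    y[rising] = -np.cos(math.pi * phi[rising] / rf)
    u = (phi[~rising] - rf) / (1 - rf)
    c = slope_scale
    y[~rising] = c * np.cos(math.pi * u) + (1 - c) * (1 - 2 * u)
    return p.amplitude_px * y


def _round_peaks(y: np.ndarray, p: PhenotypeParams, arm_amplitude: float) -> np.ndarray:
    """Blend a Gaussian-smoothed copy in near the waveform tops only, so the
    peak is rounded without disturbing troughs or excursion baselines."""
    if p.peak_rounding_s <= 0:
        return y
    sigma = p.peak_rounding_s * p.fps
    smooth = gaussian_filter1d(y, sigma, mode="nearest")
    w = np.clip(y / arm_amplitude, 0.0, 1.0) ** 2
    return (1 - w) * y + w * smooth


def _smooth_noise(rng: np.random.Generator, n: int, fps: float, cutoff_hz: float = 1.0) -> np.ndarray:
    """Unit-std low-frequency noise (Gaussian-smoothed white noise)."""
    raw = rng.standard_normal(n)
    sigma = fps / (2 * math.pi * cutoff_hz)
    sm = gaussian_filter1d(raw, sigma, mode="nearest")
    s = sm.std()
    return sm / s if s > 0 else sm


def _occlusion_bursts(rng: np.random.Generator, n: int, p: PhenotypeParams) -> np.ndarray:
    """Square-wave label-jitter bursts: 0.25–0.5 s of displacement whose sign
    alternates every 2 frames (≈ fps/4 Hz, i.e. ~15 Hz at 60 fps — above the
    rodent 9 Hz low-pass cutoff by construction, so the preset suppresses
    the burst while passing the pulling carrier)."""
    out = np.zeros(n)
    n_bursts = rng.poisson(p.occlusion_rate * p.duration_s)
    lo, hi = int(0.25 * p.fps), int(0.5 * p.fps)
    for _ in range(n_bursts):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(1, n - length)))
        k = np.arange(length)
        carrier = np.where((k // 2) % 2 == 0, 1.0, -1.0)
        envelope = np.sin(math.pi * (k + 0.5) / length) ** 2  # Hann ramp in/out
        stop = min(start + length, n)
        out[start:stop] += p.occlusion_px * (carrier * envelope)[: stop - start]
    return out


def generate_recording(
    params: PhenotypeParams,
    *,
    subject_id: str = "S00",
    session_label: str = "sim",
) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its ground truth.  Deterministic per seed."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fps))
    t = np.arange(n) / p.fps

    # draw 1: postural drift phase (shared across the body)
    drift_phase = rng.uniform(0, 2 * math.pi)
    drift = p.drift_px * np.sin(2 * math.pi * p.drift_hz * t + drift_phase)
    # draw 2: shared lateral sway
    sway = _smooth_noise(rng, n, p.fps)

    arm_phase = {"right": 0.0, "left": p.phase_offset}
    x_center = {"right": 300.0, "left": 200.0}
    tracks: dict[str, Track] = {}
    gt_troughs: dict[str, np.ndarray] = {}
    gt_peaks: dict[str, np.ndarray] = {}
    gt_amp: dict[str, float] = {}
    gt_elbow: dict[str, float] = {}

    for arm in ("right", "left"):
        injured = arm == p.injured_arm
        slope = p.pull_slope_scale if injured else 1.0
        scale = p.amplitude_scale_injured if injured else (
            p.compensation_gain if p.injured_arm != "none" else 1.0
        )
        clean = _clean_arm_waveform(t, p, arm_phase[arm], slope) * scale
        arm_amplitude = p.amplitude_px * scale
        clean = _round_peaks(clean, p, arm_amplitude)
        # per-arm draws, fixed order: x sway noise, y jitter, x jitter, occlusions
        x_noise = _smooth_noise(rng, n, p.fps) * p.indep_sway_px
        y_jit = rng.standard_normal(n) * p.jitter_px
        x_jit = rng.standard_normal(n) * p.jitter_px
        occ = _occlusion_bursts(rng, n, p)
        y = 200.0 + clean + drift + y_jit + occ
        x = x_center[arm] + p.lateral_coupling * p.sway_px * sway + x_noise + x_jit
        tracks[f"{arm}_hand"] = Track(part="hand", side=arm, x=x, y=y, fps=p.fps)

        # ground-truth cycle landmarks: troughs at cycle phase 0, peaks at rise_fraction
        phase0 = arm_phase[arm] / (2 * math.pi)
        cyc = np.arange(0, int(p.cycle_hz * p.duration_s) + 2)
        trough_t = (cyc - phase0) / p.cycle_hz
        peak_t = (cyc + p.rise_fraction - phase0) / p.cycle_hz
        gt_troughs[arm] = np.round(trough_t[(trough_t >= 0) & (trough_t < p.duration_s)] * p.fps).astype(int)
        gt_peaks[arm] = np.round(peak_t[(peak_t >= 0) & (peak_t < p.duration_s)] * p.fps).astype(int)
        gt_amp[arm] = 2 * arm_amplitude
        gt_elbow[arm] = (
            p.elbow_ratio_injured
            if (injured and p.elbow_ratio_injured is not None)
            else p.elbow_ratio
        )

        if p.species_dialect == "human":
            # per-arm elbow draws: y jitter, x jitter
            e_yjit = rng.standard_normal(n) * p.jitter_px
            e_xjit = rng.standard_normal(n) * p.jitter_px
            ey = 400.0 + gt_elbow[arm] * clean + drift + e_yjit
            ex = x_center[arm] + gt_elbow[arm] * (p.lateral_coupling * p.sway_px * sway) + e_xjit
            tracks[f"{arm}_elbow"] = Track(part="elbow", side=arm, x=ex, y=ey, fps=p.fps)

    phenotype = "healthy" if p.injured_arm == "none" else "tear"
    recording = Recording(
        subject_id=subject_id,
        session_label=session_label,
        cohort="control" if phenotype == "healthy" else "injured",
        injured_side="none" if phenotype == "healthy" else p.injured_arm,
        tracks=tracks,
        species_dialect=p.species_dialect,
        fps=p.fps,
    )
    truth = GroundTruth(
        trough_frames=gt_troughs,
        peak_frames=gt_peaks,
        amplitude_px=gt_amp,
        rise_fraction=p.rise_fraction,
        elbow_ratio=gt_elbow,
        phenotype=phenotype,
    )
    return recording, truth


def generate_cohort(
    n_control: int,
    n_tear: int,
    healthy: PhenotypeParams | None = None,
    injured: PhenotypeParams | None = None,
    trials_per_subject: int = 2,
    seed: int = 0,
    subject_cv: float = 0.1,
    species_dialect: str = "human",
) -> CohortTable:
    """Generate a labeled cohort with subject-level parameter variation.

    Each subject's base pulling frequency and amplitude are jittered by a
    seeded log-normal factor (coefficient of variation ``subject_cv``), so
    trials within a subject resemble each other more than trials across
    subjects.  All trial seeds derive from ``seed`` via a seed sequence.
    """
    if n_control < 1 or n_tear < 1:
        raise ParameterError("need at least one subject per group")
    if healthy is None:
        healthy = healthy_params(species_dialect)
    if injured is None:
        injured = tear_params(species_dialect)
    ss = np.random.SeedSequence(seed)
    recordings: list[Recording] = []
    groups = [("C", healthy, n_control), ("T", injured, n_tear)]
    sigma = math.sqrt(math.log(1 + subject_cv**2))
    for prefix, base, count in groups:
        for i in range(count):
            subj_ss = ss.spawn(1)[0]
            subj_rng = np.random.default_rng(subj_ss)
            f_hz = base.cycle_hz * math.exp(subj_rng.normal(0, sigma))
            amp = base.amplitude_px * math.exp(subj_rng.normal(0, sigma))
            subject_id = f"{prefix}{i:02d}"
            for trial in range(trials_per_subject):
                trial_seed = int(subj_rng.integers(0, 2**31 - 1))
                p = replace(base, cycle_hz=f_hz, amplitude_px=amp, seed=trial_seed)
                rec, _ = generate_recording(p, subject_id=subject_id, session_label=f"trial{trial}")
                recordings.append(rec)
    return CohortTable(
        recordings=recordings,
        provenance=f"synthetic cohort seed={seed} n_control={n_control} n_tear={n_tear}",
    )
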