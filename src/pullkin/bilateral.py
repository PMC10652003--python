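"""Bilateral coordination statistics: hand correlations, symmetry ratios,
movement dynamic-range ratio, and distribution summaries.

Hand-movement consistency is quantified by Pearson correlations of the
filtered right-vs-left x and y traces (within recording).  The movement
dynamic-range ratio — std of the low-pass-filtered, mean-centered hand
vertical trace over the same for the ipsilateral elbow — is near 1 when the
arm pivots at the shoulder and well above 1 when a stiff shoulder is
compensated by humeral rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from pullkin.errors import ConfigurationError, DegenerateInputError, InputError
from pullkin.io import Recording
from pullkin.preprocess import DIALECT_SHAPE_PRESET, apply_preset, mean_center

__all__ = [
    "BilateralSummary",
    "DistributionSummary",
    "hand_correlations",
    "dynamic_range_ratio",
    "recording_dynamic_range_ratios",
    "summarize_distribution",
]


@dataclass(frozen=True)
class BilateralSummary:
    r_x: float
    r_y: float
    reach_amplitude_ratio: float  # right:left
    reach_time_ratio: float
    pull_amplitude_ratio: float
    pull_time_ratio: float
    dynamic_range_ratio_right: float | None = None
    dynamic_range_ratio_left: float | None = None


@dataclass(frozen=True)
class DistributionSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    mean: float
    sem: float
    n: int


def hand_correlations(recording: Recording, preset: str | None = None) -> tuple[float, float]:
    """Pearson correlations of the filtered right-vs-left hand traces (x, y).

    Raises :class:`DegenerateInputError` if either filtered trace has zero
    variance (correlation undefined).
    """
    if preset is None:
        preset = DIALECT_SHAPE_PRESET[recording.species_dialect]
    r = recording.track("right_hand")
    l = recording.track("left_hand")
    out = []
    for axis in ("x", "y"):
        a = apply_preset(getattr(r, axis), recording.fps, preset)
        b = apply_preset(getattr(l, axis), recording.fps, preset)
        if a.std() == 0 or b.std() == 0:
            raise DegenerateInputError(f"zero-variance {axis} trace; correlation undefined")
        out.append(float(sstats.pearsonr(a, b).statistic))
    return out[0], out[1]


def dynamic_range_ratio(hand_y: np.ndarray, elbow_y: np.ndarray, fps: float, preset: str = "human_lowpass_only") -> float:
    """std(hand_y) / std(elbow_y) on filtered, mean-centered vertical traces."""
    hand_y = np.asarray(hand_y, dtype=float)
    elbow_y = np.asarray(elbow_y, dtype=float)
    if hand_y.shape != elbow_y.shape:
        raise InputError("hand and elbow traces must have equal length")
    h = mean_center(apply_preset(hand_y, fps, preset))
    e = mean_center(apply_preset(elbow_y, fps, preset))
    se = e.std()
    if se == 0:
        raise DegenerateInputError("elbow trace has zero variance after filtering (immobile elbow)")
    return float(h.std() / se)


def recording_dynamic_range_ratios(recording: Recording, preset: str = "human_lowpass_only") -> dict[str, float]:
    """Per-side hand:elbow dynamic-range ratios for a human recording."""
    if recording.species_dialect != "human":
        raise ConfigurationError("dynamic-range ratio requires elbow tracks (human dialect)")
    out: dict[str, float] = {}
    for side in ("right", "left"):
        out[side] = dynamic_range_ratio(
            recording.track(f"{side}_hand").y,
            recording.track(f"{side}_elbow").y,
            recording.fps,
            preset,
        )
    return out


def summarize_distribution(values: np.ndarray) -> DistributionSummary:
    """Median, quartiles (linear interpolation of order statistics), IQR,
    mean, and SEM (sample sd, n−1 denominator) of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("cannot summarize an empty sample")
    if not np.all(np.isfinite(v)):
        raise InputError("sample contains non-finite values")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0], method="linear")
    n = int(v.size)
    sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DistributionSummary(
        median=float(med), q1=float(q1), q3=float(q3), iqr=float(q3 - q1),
        mean=float(v.mean()), sem=sem, n=n,
    )
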