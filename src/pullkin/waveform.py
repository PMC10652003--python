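"""Waveform-shape biomarkers: zero-crossing peak segments, FWHM, derivatives.

The full width at half maximum (FWHM) is a hybrid fluency measure spanning the
reach-to-pull transition: the mean-centered vertical trace is cut at its
negative-to-positive and positive-to-negative zero crossings, each positive
excursion is resampled to 100 points with an interpolating 2nd-degree spline,
and the width of the peak at half its maximum is reported in fractional video
frames.  Velocity and acceleration are first and second derivatives of the
interpolated segment, in px/s and px/s².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

from pullkin.errors import InputError

__all__ = [
    "PeakSegment",
    "WaveformMetrics",
    "extract_peak_segments",
    "compute_fwhm",
    "compute_derivatives",
    "N_INTERP",
]

#: Number of spline evaluation points per segment.
N_INTERP = 100


@dataclass(frozen=True)
class PeakSegment:
    """A positive excursion of the mean-centered vertical trace.

    ``start_frame``/``end_frame`` are *fractional* frame positions of the
    bounding zero crossings (located by linear sub-sample interpolation);
    ``samples`` are the raw in-segment values; ``interpolated`` is the
    100-point spline resample on an even grid over [start_frame, end_frame].
    """

    start_frame: float
    end_frame: float
    samples: np.ndarray
    interpolated: np.ndarray
    duration: float  # seconds

    @property
    def grid_frames(self) -> np.ndarray:
        return np.linspace(self.start_frame, self.end_frame, N_INTERP)


@dataclass(frozen=True)
class WaveformMetrics:
    fwhm: float  # fractional video frames
    velocity: np.ndarray  # px/s on the interpolated grid
    acceleration: np.ndarray  # px/s² on the interpolated grid


def _check_centered(y: np.ndarray) -> None:
    s = y.std()
    if abs(y.mean()) > 1e-9 * (s if s > 0 else 1.0):
        raise InputError("input must be mean-centered")


def extract_peak_segments(y_centered: np.ndarray, fps: float, *, min_samples: int = 4) -> list[PeakSegment]:
    """Cut the mean-centered trace at zero crossings into positive excursions.

    Each segment's endpoints are the linearly interpolated sub-sample zero
    crossings; segments with fewer than ``min_samples`` in-segment frames are
    dropped.  Returns an empty list when the trace never changes sign.
    """
    y = np.asarray(y_centered, dtype=float)
    if len(y) < 3:
        raise InputError("trace too short")
    _check_centered(y)

    pos = y > 0
    # indices i where sign changes between i and i+1
    up = np.flatnonzero(~pos[:-1] & pos[1:])
    down = np.flatnonzero(pos[:-1] & ~pos[1:])
    segments: list[PeakSegment] = []
    for u in up:
        later = down[down >= u + 1]
        if len(later) == 0:
            break
        d = later[0]
        # sub-sample crossing positions by linear interpolation
        f0 = u + (0.0 - y[u]) / (y[u + 1] - y[u])
        f1 = d + (0.0 - y[d]) / (y[d + 1] - y[d])
        inner = np.arange(u + 1, d + 1)  # frames strictly inside the excursion
        # drop samples that coincide (to float precision) with a crossing knot
        inner = inner[(inner - f0 > 1e-9) & (f1 - inner > 1e-9)]
        if len(inner) < min_samples:
            continue
        knots_f = np.concatenate(([f0], inner, [f1]))
        knots_v = np.concatenate(([0.0], y[inner], [0.0]))
        spline = UnivariateSpline(knots_f, knots_v, k=2, s=0)
        grid = np.linspace(f0, f1, N_INTERP)
        interp = spline(grid)
        if interp.max() <= 0:
            continue
        segments.append(
            PeakSegment(
                start_frame=float(f0),
                end_frame=float(f1),
                samples=y[inner].copy(),
                interpolated=interp,
                duration=(f1 - f0) / fps,
            )
        )
    return segments


def _crossing(grid_idx: float, v0: float, v1: float, level: float) -> float:
    return grid_idx + (level - v0) / (v1 - v0)


def compute_fwhm(segment: PeakSegment, fps: float) -> float:
    """Width of the peak at half its maximum, in fractional video frames.

    The half-max level is half the maximum of the interpolated segment (the
    baseline is the zero line by construction).  For multimodal segments the
    width runs from the first up-crossing to the last down-crossing of the
    level.  Crossings are located by linear interpolation between grid points.
    """
    v = segment.interpolated
    peak = v.max()
    if peak <= 0:
        raise InputError("degenerate segment: non-positive maximum")
    half = peak / 2.0
    above = v >= half
    first = int(np.argmax(above))
    last = len(v) - 1 - int(np.argmax(above[::-1]))
    # sub-grid refinement of the two crossings
    left = float(first)
    if first > 0:
        left = _crossing(first - 1, v[first - 1], v[first], half)
    right = float(last)
    if last < len(v) - 1:
        right = _crossing(last, v[last], v[last + 1], half)
    frames_per_step = (segment.end_frame - segment.start_frame) / (N_INTERP - 1)
    return (right - left) * frames_per_step


def compute_derivatives(segment: PeakSegment, fps: float) -> WaveformMetrics:
    """First and second derivatives of the interpolated segment.

    Central differences on the 100-point grid with one-sided endpoints;
    the chain rule maps grid steps to seconds via the segment's duration
    (d/dt = (N−1)/duration × d/d(index)).  Velocity is signed: negative
    values are downward (pulling) motion.
    """
    dt = segment.duration / (N_INTERP - 1)
    velocity = np.gradient(segment.interpolated, dt)
    acceleration = np.gradient(velocity, dt)
    return WaveformMetrics(
        fwhm=compute_fwhm(segment, fps),
        velocity=velocity,
        acceleration=acceleration,
    )


def pooled_velocity(segments: list[PeakSegment], fps: float) -> np.ndarray:
    """Concatenate signed velocity samples across all segments of one arm."""
    if not segments:
        return np.empty(0)
    return np.concatenate([compute_derivatives(s, fps).velocity for s in segments])
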