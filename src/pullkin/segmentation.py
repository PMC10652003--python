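"""Peak/trough labeling of the vertical hand trajectory and reach/pull epochs.

A reach is the trough-to-peak (rising) phase of the vertical hand trajectory;
a pull is the peak-to-trough (falling, force-generating) phase.  Extrema are
detected with :func:`scipy.signal.find_peaks` on the filtered trace and its
negation, then merged into a strictly alternating peak/trough sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from pullkin.errors import InputError

__all__ = ["Extremum", "Epoch", "DetectionParams", "detect_extrema", "extract_epochs", "robust_amplitude"]


@dataclass(frozen=True)
class Extremum:
    frame: int
    kind: str  # "peak" | "trough"
    value: float


@dataclass(frozen=True)
class Epoch:
    """One reach or pull interval.

    ``amplitude`` is the vertical excursion in pixels (peak minus trough,
    always nonnegative); ``duration`` is the frame span divided by fps.
    """

    kind: str  # "reach" | "pull"
    start_frame: int
    end_frame: int
    amplitude: float
    duration: float


@dataclass(frozen=True)
class DetectionParams:
    """Extremum-detection settings.

    ``prominence_fraction`` scales a robust amplitude estimate (half the
    5th–95th percentile range of the filtered trace) into a prominence floor;
    ``min_separation_s`` is the minimum spacing between same-kind extrema.
    Both are scale-free so detection survives occlusion jitter without tuning.
    """

    prominence_fraction: float = 0.25
    min_separation_s: float = 0.1


def robust_amplitude(y: np.ndarray) -> float:
    """Half the [5th, 95th] percentile range — an outlier-resistant half-range."""
    lo, hi = np.percentile(y, [5.0, 95.0])
    return float(hi - lo) / 2.0


def _alternate(cands: list[Extremum]) -> list[Extremum]:
    """Enforce peak/trough alternation: within a same-kind run keep the most
    extreme candidate (ties favor the earlier one)."""
    out: list[Extremum] = []
    for e in cands:
        if out and out[-1].kind == e.kind:
            prev = out[-1]
            better = (e.value > prev.value) if e.kind == "peak" else (e.value < prev.value)
            if better:
                out[-1] = e
        else:
            out.append(e)
    return out


def detect_extrema(y: np.ndarray, fps: float, params: DetectionParams | None = None) -> list[Extremum]:
    """Label alternating peaks and troughs in a filtered vertical trace.

    Returns an empty list (rather than raising) when the trace contains no
    prominent oscillation.
    """
    if params is None:
        params = DetectionParams()
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise InputError("need at least 3 samples to detect extrema")
    prom = params.prominence_fraction * robust_amplitude(y)
    if prom <= 0:
        return []
    distance = max(1, int(round(params.min_separation_s * fps)))
    pk, _ = sps.find_peaks(y, prominence=prom, distance=distance)
    tr, _ = sps.find_peaks(-y, prominence=prom, distance=distance)
    cands = sorted(
        [Extremum(int(i), "peak", float(y[i])) for i in pk]
        + [Extremum(int(i), "trough", float(y[i])) for i in tr],
        key=lambda e: e.frame,
    )
    ext = _alternate(cands)
    if sum(e.kind == "peak" for e in ext) < 1 or sum(e.kind == "trough" for e in ext) < 1:
        return []
    return ext


def extract_epochs(extrema: list[Extremum], fps: float) -> list[Epoch]:
    """Convert an alternating extremum sequence into reach/pull epochs.

    Every trough→peak pair yields one reach and every peak→trough pair one
    pull; epochs tile the span between the first and last extremum.  Partial
    leading/trailing phases (trace starting mid-pull) are not represented —
    only extremum-bounded epochs are emitted.
    """
    epochs: list[Epoch] = []
    for a, b in zip(extrema[:-1], extrema[1:]):
        if a.kind == b.kind:
            raise InputError("extrema must alternate in kind")
        if b.frame <= a.frame:
            raise InputError("extremum frames must be strictly increasing")
        if a.kind == "trough":
            kind, amplitude = "reach", b.value - a.value
        else:
            kind, amplitude = "pull", a.value - b.value
        epochs.append(
            Epoch(
                kind=kind,
                start_frame=a.frame,
                end_frame=b.frame,
                amplitude=float(amplitude),
                duration=(b.frame - a.frame) / fps,
            )
        )
    return epochs
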