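"""Cross-frequency coupling between synergy temporal modes via bicoherence.

Bicoherence is a normalized bispectral statistic in [0, 1] that measures
phase coupling between frequency pairs (f1, f2) and their sum frequency
across spectrogram windows.  For two temporal modes the cross-bicoherence
estimator used here is

    b(f1, f2) = |Σₖ X₁ₖ(f1)·X₂ₖ(f2)·conj(X₂ₖ(f1+f2))|
                / √( Σₖ|X₁ₖ(f1)·X₂ₖ(f2)|² · Σₖ|X₂ₖ(f1+f2)|² )

over spectrogram windows k, with the sum-frequency term drawn from the second
mode, for f1 + f2 up to the Nyquist frequency.  The Cauchy–Schwarz inequality
bounds it in [0, 1].  Maps are computed on the spectrogram's native frequency
grid and bilinearly interpolated onto a fixed 0–15 Hz grid in 0.1 Hz steps so
that recordings of unequal length can be averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import RegularGridInterpolator

from pullkin.errors import InputError, ParameterError

__all__ = ["SpectralParams", "BicoherenceMap", "cross_bicoherence", "regrid_map", "band_max", "mean_map"]

GRID_MAX_HZ = 15.0
GRID_STEP_HZ = 0.1


@dataclass(frozen=True)
class SpectralParams:
    """Spectrogram settings: 2 s FFT windows with 1 s overlap by default."""

    window_s: float = 2.0
    overlap_s: float = 1.0
    window_fn: str = "hann"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.window_s:
            raise ParameterError("need 0 <= overlap_s < window_s")


@dataclass
class BicoherenceMap:
    f1_grid: np.ndarray  # Hz, strictly increasing
    f2_grid: np.ndarray
    values: np.ndarray  # len(f1_grid) × len(f2_grid), in [0, 1]
    n_windows: int


def _spectrogram(x: np.ndarray, fps: float, params: SpectralParams) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(params.window_s * fps))
    noverlap = int(round(params.overlap_s * fps))
    if nperseg < 8:
        raise ParameterError("window_s × fps must be at least 8 samples")
    f, _, X = sps.spectrogram(
        x,
        fs=fps,
        window=params.window_fn,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        mode="complex",
    )
    return f, X


def cross_bicoherence(
    mode1: np.ndarray,
    mode2: np.ndarray,
    fps: float,
    params: SpectralParams | None = None,
    *,
    fmax_hz: float = GRID_MAX_HZ,
) -> BicoherenceMap:
    """Cross-bicoherence map between two temporal modes on the native grid.

    Raises
    ------
    InputError
        If the modes differ in length or yield fewer than 4 spectrogram
        windows.
    """
    if params is None:
        params = SpectralParams()
    mode1 = np.asarray(mode1, dtype=float)
    mode2 = np.asarray(mode2, dtype=float)
    if mode1.shape != mode2.shape or mode1.ndim != 1:
        raise InputError("modes must be 1-D arrays of equal length")
    f, X1 = _spectrogram(mode1, fps, params)
    _, X2 = _spectrogram(mode2, fps, params)
    n_windows = X1.shape[1]
    if n_windows < 4:
        raise InputError(f"only {n_windows} spectrogram windows; need at least 4")

    n_axis = int(np.searchsorted(f, fmax_hz, side="right"))
    n_full = len(f)
    values = np.zeros((n_axis, n_axis))
    p2 = np.mean(np.abs(X2) ** 2, axis=1)  # per-frequency power of mode2
    for i in range(n_axis):
        j_max = min(n_axis, n_full - i)  # f1 + f2 must stay on the grid (≤ Nyquist)
        if j_max <= 0:
            continue
        a = X1[i, :][None, :] * X2[:j_max, :]  # (j, k)
        b = np.conj(X2[i : i + j_max, :])  # X2 at the sum frequency
        num = np.abs(np.sum(a * b, axis=1))
        den = np.sqrt(np.sum(np.abs(a) ** 2, axis=1) * n_windows * p2[i : i + j_max])
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(den > 0, num / den, 0.0)
        values[i, :j_max] = np.clip(v, 0.0, 1.0)  # guard float overshoot of the CS bound
    return BicoherenceMap(f1_grid=f[:n_axis].copy(), f2_grid=f[:n_axis].copy(), values=values, n_windows=n_windows)


def regrid_map(bmap: BicoherenceMap, *, fmax_hz: float = GRID_MAX_HZ, step_hz: float = GRID_STEP_HZ) -> BicoherenceMap:
    """Bilinearly interpolate a native-grid map onto the fixed 0–15 Hz grid.

    Query points outside the native grid are clamped to its edge (recorded
    behavior for recordings whose Nyquist falls below the grid maximum).
    """
    grid = np.round(np.arange(0.0, fmax_hz + step_hz / 2, step_hz), 10)
    interp = RegularGridInterpolator(
        (bmap.f1_grid, bmap.f2_grid), bmap.values, method="linear", bounds_error=False
    )
    q1 = np.clip(grid, bmap.f1_grid[0], bmap.f1_grid[-1])
    q2 = np.clip(grid, bmap.f2_grid[0], bmap.f2_grid[-1])
    pts = np.stack(np.meshgrid(q1, q2, indexing="ij"), axis=-1)
    return BicoherenceMap(
        f1_grid=grid, f2_grid=grid.copy(), values=interp(pts), n_windows=bmap.n_windows
    )


def band_max(bmap: BicoherenceMap, band_hz: tuple[float, float], *, convention: str = "both_axes") -> float:
    """Maximum bicoherence over a frequency band.

    ``convention="both_axes"`` (default) takes the maximum over grid nodes
    with both f1 and f2 inside the band; ``"sum_in_band"`` instead requires
    f1 + f2 inside the band.
    """
    lo, hi = band_hz
    if lo < bmap.f1_grid[0] or hi > bmap.f1_grid[-1] + 1e-9:
        raise ParameterError(f"band {band_hz} outside grid range")
    m1 = (bmap.f1_grid >= lo) & (bmap.f1_grid <= hi)
    m2 = (bmap.f2_grid >= lo) & (bmap.f2_grid <= hi)
    if convention == "both_axes":
        sub = bmap.values[np.ix_(m1, m2)]
    elif convention == "sum_in_band":
        fsum = bmap.f1_grid[:, None] + bmap.f2_grid[None, :]
        sub = bmap.values[(fsum >= lo) & (fsum <= hi)]
    else:
        raise ParameterError(f"unknown convention {convention!r}")
    if sub.size == 0:
        raise ParameterError("band contains no grid nodes")
    return float(sub.max())


def mean_map(maps: list[BicoherenceMap]) -> BicoherenceMap:
    """Arithmetic mean of maps sharing the fixed grid (across recordings)."""
    if not maps:
        raise InputError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if not (np.array_equal(m.f1_grid, first.f1_grid) and np.array_equal(m.f2_grid, first.f2_grid)):
            raise InputError("maps must share a common grid; regrid first")
    return BicoherenceMap(
        f1_grid=first.f1_grid.copy(),
        f2_grid=first.f2_grid.copy(),
        values=np.mean([m.values for m in maps], axis=0),
        n_windows=min(m.n_windows for m in maps),
    )
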