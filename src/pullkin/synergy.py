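"""Kinematic synergies via singular value decomposition.

The filtered, mean-centered coordinate channels of one recording are stacked
into a channels × frames matrix T (rodent: R_X, R_Y, L_X, L_Y; human: hands
plus elbows, 8 channels) and decomposed as T = U·S·Vᵀ.  Columns of U are the
kinematic synergies (covariation patterns across channels), the squared
singular values give the variance explained by each component, and rows of Vᵀ
are the temporal modes — each component's activation time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pullkin.errors import ConfigurationError, InputError
from pullkin.io import Recording
from pullkin.preprocess import DIALECT_SHAPE_PRESET, apply_preset, mean_center

__all__ = [
    "KinematicMatrix",
    "SynergyDecomposition",
    "RODENT_CHANNELS",
    "HUMAN_CHANNELS",
    "build_matrix",
    "decompose",
    "abs_weights",
    "cumulative_variance",
]

#: Channel order conventions.  "R_Y" = right hand vertical, etc.
RODENT_CHANNELS = ("R_X", "R_Y", "L_X", "L_Y")
HUMAN_CHANNELS = ("R_X", "R_Y", "L_X", "L_Y", "RE_X", "RE_Y", "LE_X", "LE_Y")

_CHANNEL_SOURCE = {
    "R_X": ("right_hand", "x"), "R_Y": ("right_hand", "y"),
    "L_X": ("left_hand", "x"), "L_Y": ("left_hand", "y"),
    "RE_X": ("right_elbow", "x"), "RE_Y": ("right_elbow", "y"),
    "LE_X": ("left_elbow", "x"), "LE_Y": ("left_elbow", "y"),
}


@dataclass
class KinematicMatrix:
    channels: tuple[str, ...]
    data: np.ndarray  # channels × frames, each row mean-centered
    fps: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise InputError("data must be channels × frames")
        if self.data.shape[0] < 2 or self.data.shape[1] <= self.data.shape[0]:
            raise InputError("need >= 2 channels and more frames than channels")
        scale = np.abs(self.data).max() or 1.0
        if np.abs(self.data.mean(axis=1)).max() > 1e-6 * scale:
            raise InputError("every row must be mean-centered")


@dataclass
class SynergyDecomposition:
    channels: tuple[str, ...]
    weights: np.ndarray  # channels × channels; columns are components (U)
    singular_values: np.ndarray  # descending (diagonal of S)
    temporal_modes: np.ndarray  # components × frames (Vᵀ)
    variance_explained: np.ndarray  # per-component fractions, sums to 1

    def reconstruct(self) -> np.ndarray:
        return (self.weights * self.singular_values) @ self.temporal_modes


def build_matrix(
    recording: Recording,
    channels: tuple[str, ...] | None = None,
    preset: str | None = None,
) -> KinematicMatrix:
    """Filter, mean-center, and stack a recording's coordinate channels.

    Defaults: rodent recordings use the 4 hand channels with the
    ``rodent_full`` preset; human recordings use all 8 hand+elbow channels
    with ``human_lowpass_only`` (human traces are clean enough that only
    low-pass filtering is applied before decomposition).
    """
    if channels is None:
        channels = RODENT_CHANNELS if recording.species_dialect == "rodent" else HUMAN_CHANNELS
    if preset is None:
        preset = DIALECT_SHAPE_PRESET[recording.species_dialect]
    rows = []
    for ch in channels:
        if ch not in _CHANNEL_SOURCE:
            raise ConfigurationError(f"unknown channel {ch!r}")
        label, axis = _CHANNEL_SOURCE[ch]
        if label not in recording.tracks:
            raise ConfigurationError(f"channel {ch!r} requires missing track {label!r}")
        trace = getattr(recording.tracks[label], axis)
        rows.append(mean_center(apply_preset(trace, recording.fps, preset)))
    return KinematicMatrix(channels=tuple(channels), data=np.vstack(rows), fps=recording.fps)


def decompose(matrix: KinematicMatrix) -> SynergyDecomposition:
    """Economy SVD of the channels × frames matrix.

    variance_explained[i] = sᵢ² / Σⱼ sⱼ².  For reproducibility each weight
    column's largest-magnitude entry is made positive (sign of a singular
    vector pair is arbitrary; downstream analyses use absolute weights).
    """
    u, s, vt = np.linalg.svd(matrix.data, full_matrices=False)
    # deterministic sign convention
    for j in range(u.shape[1]):
        k = int(np.argmax(np.abs(u[:, j])))
        if u[k, j] < 0:
            u[:, j] *= -1.0
            vt[j, :] *= -1.0
    total = float(np.sum(s**2))
    if total == 0:
        raise InputError("zero matrix has no synergy structure")
    return SynergyDecomposition(
        channels=matrix.channels,
        weights=u,
        singular_values=s,
        temporal_modes=vt,
        variance_explained=s**2 / total,
    )


def abs_weights(decomp: SynergyDecomposition, component: int, channels: tuple[str, ...] | None = None) -> dict[str, float]:
    """Absolute channel weights |U[channel, component]| for one component.

    The sign of an eigenvector is relative, so only magnitudes are
    meaningful for comparing channel contributions.
    """
    if not 0 <= component < decomp.weights.shape[1]:
        raise ConfigurationError(f"component {component} out of range")
    if channels is None:
        channels = decomp.channels
    out: dict[str, float] = {}
    for ch in channels:
        if ch not in decomp.channels:
            raise ConfigurationError(f"unknown channel {ch!r}")
        out[ch] = float(abs(decomp.weights[decomp.channels.index(ch), component]))
    return out


def cumulative_variance(decomp: SynergyDecomposition, k: int) -> float:
    """Fraction of variance captured by the first k components."""
    if not 1 <= k <= len(decomp.variance_explained):
        raise ConfigurationError(f"k={k} out of range")
    return float(np.sum(decomp.variance_explained[:k]))
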