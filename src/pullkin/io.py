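"""Trajectory I/O: pose-table reading/writing, quality control, coordinate conventions.

Two table dialects are supported:

* the three-header-row pose-estimation dialect (``scorer`` / ``bodyparts`` /
  ``coords``) produced by markerless tracking tools, with one column triple
  (x, y, likelihood) per labeled bodypart, y in image coordinates
  (down-positive);
* a flat dialect with columns ``frame, <part>_x, <part>_y[, <part>_likelihood]``
  and y already up-positive — the package's own output format.

On load, image-coordinate y is converted to up-positive (``frame_height - y``)
so that "reach" is a rising excursion and "pull" a falling one throughout the
pipeline.  Frame indexing is 0-based; times are ``frame / fps`` seconds.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pullkin.errors import FormatError, InputError, StructuralError

__all__ = [
    "Track",
    "Recording",
    "CohortTable",
    "read_pose_table",
    "write_recording",
    "read_flat_recording",
    "flag_jumps",
    "DEFAULT_JUMP_THRESHOLD_PX",
]

#: Outlier-jump flagging thresholds (pixels) per species dialect: the Euclidean
#: displacement between consecutively labeled points beyond which a frame is
#: treated as a labeling jump.
DEFAULT_JUMP_THRESHOLD_PX = {"rodent": 10.0, "human": 20.0}

_SIDE_ALIASES = {"r": "right", "right": "right", "l": "left", "left": "left"}
_PART_ALIASES = {"hand": "hand", "paw": "hand", "wrist": "hand", "elbow": "elbow"}


def _parse_bodypart(label: str) -> tuple[str, str]:
    """Map a free-form bodypart label to (side, part).

    Accepts e.g. ``rhand``, ``right_hand``, ``hand_l``, ``LeftElbow``.
    """
    s = re.sub(r"[^a-z]", " ", label.lower()).strip()
    tokens = s.split() if " " in s else None
    if tokens is None:
        # glued form like "rhand" or "lefthand"
        m = re.match(r"^(r|l|right|left)(hand|paw|wrist|elbow)$", s)
        if not m:
            m = re.match(r"^(hand|paw|wrist|elbow)(r|l|right|left)$", s)
            if not m:
                raise FormatError(f"cannot parse bodypart label {label!r}")
            part_tok, side_tok = m.group(1), m.group(2)
        else:
            side_tok, part_tok = m.group(1), m.group(2)
    else:
        side_tok = next((t for t in tokens if t in _SIDE_ALIASES), None)
        part_tok = next((t for t in tokens if t in _PART_ALIASES), None)
        if side_tok is None or part_tok is None:
            raise FormatError(f"cannot parse bodypart label {label!r}")
    return _SIDE_ALIASES[side_tok], _PART_ALIASES[part_tok]


@dataclass
class Track:
    """One bodypart's pixel trajectory at a fixed frame rate.

    ``y`` is up-positive.  ``likelihood`` is retained for provenance only and
    never used for filtering.
    """

    part: str  # "hand" | "elbow"
    side: str  # "left" | "right"
    x: np.ndarray
    y: np.ndarray
    fps: float
    likelihood: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.part not in ("hand", "elbow"):
            raise InputError(f"unknown part {self.part!r}")
        if self.side not in ("left", "right"):
            raise InputError(f"unknown side {self.side!r}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise StructuralError("x and y must be 1-D arrays of identical length")
        if len(self.x) < 2:
            raise StructuralError("a track needs at least 2 frames")
        if self.fps <= 0:
            raise InputError("fps must be positive")
        if self.likelihood is not None:
            self.likelihood = np.asarray(self.likelihood, dtype=float)
            if self.likelihood.shape != self.x.shape:
                raise StructuralError("likelihood length must match x/y")
            if np.nanmin(self.likelihood) < 0 or np.nanmax(self.likelihood) > 1:
                raise InputError("likelihood values must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.side}_{self.part}"

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class Recording:
    """A subject-session bundle of tracks plus metadata."""

    subject_id: str
    session_label: str
    cohort: str  # "control" | "injured"
    injured_side: str  # "left" | "right" | "none"
    tracks: dict[str, Track]  # keyed by Track.label
    species_dialect: str  # "rodent" | "human"
    fps: float

    def __post_init__(self) -> None:
        if self.cohort not in ("control", "injured"):
            raise InputError(f"unknown cohort {self.cohort!r}")
        if self.injured_side not in ("left", "right", "none"):
            raise InputError(f"unknown injured_side {self.injured_side!r}")
        if (self.injured_side == "none") != (self.cohort == "control"):
            raise InputError("injured_side must be 'none' iff cohort is 'control'")
        if self.species_dialect not in ("rodent", "human"):
            raise InputError(f"unknown dialect {self.species_dialect!r}")
        lengths = {t.n_frames for t in self.tracks.values()}
        fpss = {t.fps for t in self.tracks.values()}
        if len(lengths) > 1 or len(fpss) > 1:
            raise StructuralError("all tracks must share length and fps")
        if self.tracks and fpss != {self.fps}:
            raise StructuralError("track fps disagrees with recording fps")
        parts = {t.part for t in self.tracks.values()}
        if self.species_dialect == "rodent" and "elbow" in parts:
            raise StructuralError("rodent dialect carries hand tracks only")

    @property
    def n_frames(self) -> int:
        return next(iter(self.tracks.values())).n_frames

    def track(self, label: str) -> Track:
        try:
            return self.tracks[label]
        except KeyError:
            raise KeyError(f"recording has no track {label!r}; available: {sorted(self.tracks)}")

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}/{self.session_label}"


@dataclass
class CohortTable:
    """An ordered collection of recordings with free-text provenance."""

    recordings: list[Recording]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.recordings)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            seen.setdefault(r.subject_id, None)
        return list(seen)


def _read_dlc_dialect(path, fps: float, frame_height: float) -> dict[str, Track]:
    header = pd.read_csv(path, nrows=3, header=None)
    first_col = [str(v).strip().lower() for v in header.iloc[:, 0]]
    if first_col[:3] != ["scorer", "bodyparts", "coords"]:
        raise FormatError(
            "expected three header rows named scorer/bodyparts/coords; "
            f"found first column {first_col[:3]}"
        )
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    tracks: dict[str, Track] = {}
    bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
    for bp in bodyparts:
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        cols = {str(c).strip().lower() for c in sub.columns}
        if not {"x", "y"} <= cols:
            raise FormatError(f"bodypart {bp!r} lacks x/y coordinate columns")
        side, part = _parse_bodypart(bp)
        lik = sub["likelihood"].to_numpy(float) if "likelihood" in cols else None
        tr = Track(
            part=part,
            side=side,
            x=sub["x"].to_numpy(float),
            y=frame_height - sub["y"].to_numpy(float),  # flip to up-positive
            fps=fps,
            likelihood=lik,
        )
        tracks[tr.label] = tr
    return tracks


def _read_flat_dialect(path, fps: float) -> dict[str, Track]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if "frame" not in cols:
        raise FormatError("flat dialect requires a 'frame' column")
    part_names = sorted({c[:-2] for c in cols if c.endswith("_x")})
    if not part_names:
        raise FormatError("flat dialect requires <part>_x/<part>_y columns")
    tracks: dict[str, Track] = {}
    for name in part_names:
        if f"{name}_y" not in cols:
            raise StructuralError(f"column {name}_x present without {name}_y")
        side, part = _parse_bodypart(name)
        lik_col = f"{name}_likelihood"
        tr = Track(
            part=part,
            side=side,
            x=df[f"{name}_x"].to_numpy(float),
            y=df[f"{name}_y"].to_numpy(float),  # flat dialect is already up-positive
            fps=fps,
            likelihood=df[lik_col].to_numpy(float) if lik_col in cols else None,
        )
        tracks[tr.label] = tr
    return tracks


def read_pose_table(
    path,
    *,
    fps: float,
    subject_id: str,
    session_label: str = "",
    cohort: str = "control",
    injured_side: str = "none",
    species_dialect: str = "rodent",
    dialect: str = "auto",
    frame_height: float = 1080.0,
) -> Recording:
    """Read a trajectory table into a :class:`Recording`.

    Parameters
    ----------
    dialect
        ``"pose"`` for the three-header-row pose-estimation dialect, ``"flat"``
        for the flat dialect, or ``"auto"`` to sniff from the first cell.
    frame_height
        Video height in pixels, used to flip pose-dialect y to up-positive.
    """
    if dialect == "auto":
        with open(path) as fh:
            first = fh.readline().split(",")[0].strip().lower()
        dialect = "pose" if first == "scorer" else "flat"
    if dialect == "pose":
        tracks = _read_dlc_dialect(path, fps, frame_height)
    elif dialect == "flat":
        tracks = _read_flat_dialect(path, fps)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return Recording(
        subject_id=subject_id,
        session_label=session_label,
        cohort=cohort,
        injured_side=injured_side,
        tracks=tracks,
        species_dialect=species_dialect,
        fps=fps,
    )


def write_recording(recording: Recording, csv_path, meta_path=None) -> None:
    """Write a recording as flat CSV plus an optional JSON metadata sidecar.

    Floats are written with ``repr`` round-trip precision so that a
    write/read cycle reproduces the numeric payload bit-exactly.
    """
    data: dict[str, np.ndarray] = {"frame": np.arange(recording.n_frames)}
    for label in sorted(recording.tracks):
        tr = recording.tracks[label]
        data[f"{label}_x"] = tr.x
        data[f"{label}_y"] = tr.y
        if tr.likelihood is not None:
            data[f"{label}_likelihood"] = tr.likelihood
    pd.DataFrame(data).to_csv(csv_path, index=False, float_format="%.17g")
    if meta_path is not None:
        meta = {
            "subject_id": recording.subject_id,
            "session_label": recording.session_label,
            "cohort": recording.cohort,
            "injured_side": recording.injured_side,
            "species_dialect": recording.species_dialect,
            "fps": recording.fps,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def read_flat_recording(csv_path, meta_path) -> Recording:
    """Read a flat CSV written by :func:`write_recording` plus its sidecar."""
    with open(meta_path) as fh:
        meta = json.load(fh)
    return read_pose_table(
        csv_path,
        fps=meta["fps"],
        subject_id=meta["subject_id"],
        session_label=meta["session_label"],
        cohort=meta["cohort"],
        injured_side=meta["injured_side"],
        species_dialect=meta["species_dialect"],
        dialect="flat",
    )


def flag_jumps(track: Track, threshold_px: float | None = None, *, dialect: str = "rodent") -> list[int]:
    """Flag frames whose Euclidean displacement from the previous labeled
    point is at least ``threshold_px``.

    Frames with displacement exactly at the threshold are flagged (the
    criterion is inclusive).  Returns 0-based indices of the *later* frame of
    each offending pair.
    """
    if threshold_px is None:
        threshold_px = DEFAULT_JUMP_THRESHOLD_PX[dialect]
    if threshold_px <= 0:
        raise InputError("threshold_px must be positive")
    if track.n_frames < 2:
        raise InputError("track must have at least 2 frames")
    d = np.hypot(np.diff(track.x), np.diff(track.y))
    return [int(i) + 1 for i in np.flatnonzero(d >= threshold_px)]


def flipped_y(track: Track, frame_height: float) -> Track:
    """Return a copy of the track with y mirrored about the frame midline."""
    return replace(track, y=frame_height - track.y)
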