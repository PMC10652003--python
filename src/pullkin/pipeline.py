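"""End-to-end orchestration: extract biomarker tables from recordings and
summarize them into a report.

Stage outputs are plain CSV/JSON so each stage can be inspected and tested
in isolation.  All randomness flows from the run seed; outputs are identical
for identical config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pullkin import __version__
from pullkin.bicoherence import SpectralParams, band_max, cross_bicoherence, regrid_map
from pullkin.bilateral import hand_correlations, summarize_distribution
from pullkin.classifier import ClassifierConfig, assemble_features, features_to_frame, fit_evaluate
from pullkin.errors import PullkinError
from pullkin.io import Recording, read_flat_recording
from pullkin.preprocess import DIALECT_PRESET, apply_preset, mean_center
from pullkin.segmentation import DetectionParams, detect_extrema, extract_epochs
from pullkin.synergy import abs_weights, build_matrix, cumulative_variance, decompose
from pullkin.waveform import compute_fwhm, extract_peak_segments
from pullkin.preprocess import DIALECT_SHAPE_PRESET

log = logging.getLogger("pullkin")

__all__ = ["RunConfig", "run_extract", "run_report", "load_recordings"]


@dataclass
class RunConfig:
    input_dir: str | None = None
    out_dir: str = "pullkin_out"
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    coupling_band_hz: tuple[float, float] = (2.0, 4.0)
    strict: bool = False

    def digest(self) -> str:
        payload = json.dumps(
            {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v) for k, v in vars(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_recordings(input_dir: str | Path) -> list[Recording]:
    """Load every flat-CSV recording with a ``.meta.json`` sidecar."""
    input_dir = Path(input_dir)
    recs = []
    for csv_path in sorted(input_dir.glob("*.csv")):
        meta_path = input_dir / (csv_path.stem + ".meta.json")
        if meta_path.exists():
            recs.append(read_flat_recording(csv_path, meta_path))
    return recs


def _extract_one(rec: Recording, config: RunConfig, tables: dict[str, list]) -> None:
    fps = rec.fps
    rid = rec.recording_id
    hands = [lbl for lbl in sorted(rec.tracks) if rec.tracks[lbl].part == "hand"]
    for lbl in hands:
        y = apply_preset(rec.tracks[lbl].y, fps, DIALECT_PRESET[rec.species_dialect])
        epochs = extract_epochs(detect_extrema(y, fps, config.detection), fps)
        for e in epochs:
            tables["epochs"].append(
                dict(recording_id=rid, bodypart=lbl, kind=e.kind, start_frame=e.start_frame,
                     end_frame=e.end_frame, amplitude_px=e.amplitude, duration_s=e.duration)
            )
        y_shape = mean_center(apply_preset(rec.tracks[lbl].y, fps, DIALECT_SHAPE_PRESET[rec.species_dialect]))
        for i, seg in enumerate(extract_peak_segments(y_shape, fps)):
            tables["waveform"].append(
                dict(recording_id=rid, bodypart=lbl, segment_index=i,
                     fwhm_frames=compute_fwhm(seg, fps))
            )

    r_x, r_y = hand_correlations(rec)
    tables["bilateral"].append(dict(recording_id=rid, r_x=r_x, r_y=r_y))

    matrix = build_matrix(rec)
    decomp = decompose(matrix)
    tables["synergy"][rid] = {
        "channels": list(decomp.channels),
        "variance_explained": decomp.variance_explained.tolist(),
        "cumulative_k2": cumulative_variance(decomp, min(2, len(decomp.channels))),
        "abs_weights_pc1": abs_weights(decomp, 0),
    }
    try:
        bmap = regrid_map(cross_bicoherence(
            decomp.temporal_modes[0], decomp.temporal_modes[1], fps, config.spectral
        ))
        tables["bicoherence"].append(
            dict(recording_id=rid, band_max=band_max(bmap, config.coupling_band_hz),
                 n_windows=bmap.n_windows)
        )
    except PullkinError as exc:
        log.warning("bicoherence skipped for %s: %s", rid, exc)

    fv = assemble_features(rec, config.detection)
    tables["features"].append(fv)


def run_extract(recordings: list[Recording], config: RunConfig) -> dict[str, Path]:
    """Run every extraction stage over a list of recordings.

    Per-recording failures are logged and collected in a failure manifest
    (or re-raised with ``strict=True``); outputs are written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict = {"epochs": [], "waveform": [], "bilateral": [], "bicoherence": [],
                    "synergy": {}, "features": []}
    failures: list[dict] = []
    for rec in recordings:
        try:
            _extract_one(rec, config, tables)
            log.info("extracted %s", rec.recording_id)
        except Exception as exc:
            if config.strict:
                raise
            failures.append({"recording_id": rec.recording_id, "error": str(exc)})
            log.warning("skipped %s: %s", rec.recording_id, exc)

    paths: dict[str, Path] = {}
    for name in ("epochs", "waveform", "bilateral", "bicoherence"):
        paths[name] = out / f"{name}.csv"
        pd.DataFrame(tables[name]).to_csv(paths[name], index=False)
    paths["synergy"] = out / "synergy.json"
    with open(paths["synergy"], "w") as fh:
        json.dump(tables["synergy"], fh, indent=2)
    paths["features"] = out / "features.csv"
    features_to_frame(tables["features"]).to_csv(paths["features"], index=False)
    paths["failures"] = out / "failures.json"
    with open(paths["failures"], "w") as fh:
        json.dump({"n_failed": len(failures), "failures": failures}, fh, indent=2)
    paths["provenance"] = out / "provenance.json"
    with open(paths["provenance"], "w") as fh:
        json.dump({"pullkin_version": __version__, "seed": config.seed,
                   "config_digest": config.digest(),
                   "n_recordings": len(recordings), "n_failed": len(failures)}, fh, indent=2)
    return paths


def run_report(config: RunConfig) -> dict:
    """Summarize extract outputs into a JSON-serializable report."""
    out = Path(config.out_dir)
    features = pd.read_csv(out / "features.csv")
    bilateral = pd.read_csv(out / "bilateral.csv")
    report: dict = {
        "provenance": json.load(open(out / "provenance.json")),
        "groups": {},
    }
    if not bilateral.empty:
        for col in ("r_x", "r_y"):
            report[f"hand_correlation_{col}"] = asdict(summarize_distribution(bilateral[col].to_numpy()))
    if not features.empty:
        for label, sub in features.groupby("label"):
            group: dict = {"n_recordings": int(len(sub)), "n_subjects": int(sub["subject_id"].nunique())}
            for col in sub.columns:
                if sub[col].dtype.kind in "fi":
                    group[col] = asdict(summarize_distribution(sub[col].to_numpy()))
            report["groups"][label] = group
    labels = set(features["label"].unique()) if not features.empty else set()
    if {"tear", "no_tear"} <= labels:
        model = fit_evaluate(features, config.classifier)
        report["classifier"] = {
            "auc_mean": model.auc_mean,
            "auc_sd": model.auc_sd,
            "sensitivity_mean": model.sensitivity_mean,
            "specificity_mean": model.specificity_mean,
            "fold_aucs": model.fold_aucs.tolist(),
        }
    else:
        report["classifier"] = "not-applicable (need both cohorts)"
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
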