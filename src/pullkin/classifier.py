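"""Biomarker feature assembly and the regularized injury classifier.

For each recording, per-arm means of reach/pull time and amplitude, FWHM and
signed velocity are combined with right:left symmetry ratios and (human
dialect) per-arm hand:elbow dynamic-range ratios into one feature vector.
Classification uses L2-penalized logistic regression (default C = 0.001,
saga solver) under stratified 3-fold cross-validation; because C this small
is meaningless across mixed units (pixels vs seconds), features are z-scored
with statistics fit on each training fold.  Folds are grouped by subject by
default so one participant's trials never straddle the train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from pullkin.bilateral import recording_dynamic_range_ratios
from pullkin.errors import DegenerateInputError, InputError, ParameterError
from pullkin.io import Recording
from pullkin.preprocess import DIALECT_PRESET, DIALECT_SHAPE_PRESET, apply_preset, mean_center
from pullkin.segmentation import DetectionParams, detect_extrema, extract_epochs
from pullkin.waveform import compute_derivatives, compute_fwhm, extract_peak_segments

__all__ = ["FeatureVector", "ClassifierConfig", "ModelReport", "assemble_features", "features_to_frame", "fit_evaluate"]

ARM_FEATURES = (
    "mean_reach_time_s",
    "mean_pull_time_s",
    "mean_reach_amplitude_px",
    "mean_pull_amplitude_px",
    "mean_fwhm_frames",
    "mean_velocity_px_s",
)
RATIO_FEATURES = (
    "reach_amplitude_ratio",
    "reach_time_ratio",
    "pull_amplitude_ratio",
    "pull_time_ratio",
)


@dataclass
class FeatureVector:
    recording_id: str
    subject_id: str
    label: str  # "no_tear" | "tear"
    features: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ClassifierConfig:
    l2_C: float = 0.001
    n_folds: int = 3
    seed: int = 0
    standardize: bool = True
    group_by_subject: bool = True
    solver: str = "saga"

    def __post_init__(self) -> None:
        if self.l2_C <= 0:
            raise ParameterError("l2_C must be positive")
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")


@dataclass
class ModelReport:
    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_sd: np.ndarray
    fold_aucs: np.ndarray
    auc_mean: float
    auc_sd: float
    sensitivity_mean: float
    specificity_mean: float
    fold_assignments: list[np.ndarray]


def _arm_metrics(recording: Recording, side: str, detection: DetectionParams) -> dict[str, float]:
    fps = recording.fps
    y_raw = recording.track(f"{side}_hand").y
    y_epochs = apply_preset(y_raw, fps, DIALECT_PRESET[recording.species_dialect])
    extrema = detect_extrema(y_epochs, fps, detection)
    epochs = extract_epochs(extrema, fps)
    reaches = [e for e in epochs if e.kind == "reach"]
    pulls = [e for e in epochs if e.kind == "pull"]
    if not reaches or not pulls:
        raise DegenerateInputError(f"no epochs detected on {side} arm")
    y_shape = mean_center(apply_preset(y_raw, fps, DIALECT_SHAPE_PRESET[recording.species_dialect]))
    segments = extract_peak_segments(y_shape, fps)
    if not segments:
        raise DegenerateInputError(f"no peak segments on {side} arm")
    fwhms = [compute_fwhm(s, fps) for s in segments]
    velocity = np.concatenate([compute_derivatives(s, fps).velocity for s in segments])
    return {
        "mean_reach_time_s": float(np.mean([e.duration for e in reaches])),
        "mean_pull_time_s": float(np.mean([e.duration for e in pulls])),
        "mean_reach_amplitude_px": float(np.mean([e.amplitude for e in reaches])),
        "mean_pull_amplitude_px": float(np.mean([e.amplitude for e in pulls])),
        "mean_fwhm_frames": float(np.mean(fwhms)),
        "mean_velocity_px_s": float(np.mean(velocity)),
    }


def assemble_features(recording: Recording, detection: DetectionParams | None = None) -> FeatureVector:
    """Compute the per-recording biomarker feature vector.

    Raises :class:`DegenerateInputError` when an arm yields no epochs; the
    caller decides whether to exclude the recording or abort.
    """
    if detection is None:
        detection = DetectionParams()
    per_arm = {side: _arm_metrics(recording, side, detection) for side in ("right", "left")}
    feats: dict[str, float] = {}
    for side in ("right", "left"):
        for name, value in per_arm[side].items():
            feats[f"{side}_{name}"] = value
    for ratio_name, base in zip(
        RATIO_FEATURES,
        ("mean_reach_amplitude_px", "mean_reach_time_s", "mean_pull_amplitude_px", "mean_pull_time_s"),
    ):
        denom = per_arm["left"][base]
        if denom == 0:
            raise DegenerateInputError(f"left-arm {base} is zero; symmetry ratio undefined")
        feats[ratio_name] = per_arm["right"][base] / denom
    if recording.species_dialect == "human":
        drr = recording_dynamic_range_ratios(recording)
        feats["right_dynamic_range_ratio"] = drr["right"]
        feats["left_dynamic_range_ratio"] = drr["left"]
    bad = [k for k, v in feats.items() if not np.isfinite(v)]
    if bad:
        raise InputError(f"non-finite features {bad} in recording {recording.recording_id}")
    return FeatureVector(
        recording_id=recording.recording_id,
        subject_id=recording.subject_id,
        label="tear" if recording.cohort == "injured" else "no_tear",
        features=feats,
    )


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a tidy table (one row per recording)."""
    rows = []
    for fv in vectors:
        row = {"recording_id": fv.recording_id, "subject_id": fv.subject_id, "label": fv.label}
        row.update(fv.features)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_evaluate(table: pd.DataFrame, config: ClassifierConfig | None = None) -> ModelReport:
    """Cross-validated ROC/AUC of the L2 logistic classifier.

    ``table`` needs a binary ``label`` column ("tear"/"no_tear"), a
    ``subject_id`` column when grouping, and numeric feature columns.
    The mean ROC is a vertical average of per-fold curves on a fixed
    false-positive-rate grid; sensitivity/specificity are evaluated at the
    0.5 predicted-probability threshold and averaged across folds.
    """
    if config is None:
        config = ClassifierConfig()
    feature_cols = [c for c in table.columns if c not in ("recording_id", "subject_id", "label")]
    X = table[feature_cols].to_numpy(float)
    if not np.all(np.isfinite(X)):
        bad_rows = np.flatnonzero(~np.isfinite(X).all(axis=1))
        j = np.flatnonzero(~np.isfinite(X[bad_rows[0]]))[0]
        rid = table.iloc[bad_rows[0]].get("recording_id", bad_rows[0])
        raise InputError(f"non-finite feature {feature_cols[j]!r} in recording {rid!r}")
    y = (table["label"] == "tear").to_numpy(int)
    if len(np.unique(y)) < 2:
        raise InputError("both classes must be present")

    if config.group_by_subject:
        if "subject_id" not in table.columns:
            raise InputError("group_by_subject requires a subject_id column")
        cv = StratifiedGroupKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
        groups = table["subject_id"].to_numpy()
    else:
        cv = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
        groups = None

    fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs, aucs, sens, spec, folds = [], [], [], [], []
    for train, test in cv.split(X, y, groups):
        if len(np.unique(y[train])) < 2:
            raise InputError("stratification failed: single-class training fold")
        if len(np.unique(y[test])) < 2:
            raise InputError("stratification failed: single-class test fold")
        steps = []
        if config.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(
            (
                "logreg",
                LogisticRegression(
                    C=config.l2_C, solver=config.solver,  # default penalty is L2
                    max_iter=10000, random_state=config.seed,
                ),
            )
        )
        model = Pipeline(steps).fit(X[train], y[train])
        scores = model.predict_proba(X[test])[:, 1]
        fpr, tpr, _ = roc_curve(y[test], scores)
        aucs.append(auc(fpr, tpr))
        interp = np.interp(fpr_grid, fpr, tpr)
        interp[0] = 0.0
        interp[-1] = 1.0
        tprs.append(interp)
        pred = (scores >= 0.5).astype(int)
        pos, neg = y[test] == 1, y[test] == 0
        sens.append(float(np.mean(pred[pos] == 1)))
        spec.append(float(np.mean(pred[neg] == 0)))
        folds.append(np.asarray(test))

    tprs = np.asarray(tprs)
    return ModelReport(
        fpr_grid=fpr_grid,
        tpr_mean=tprs.mean(axis=0),
        tpr_sd=tprs.std(axis=0, ddof=1) if len(tprs) > 1 else np.zeros_like(fpr_grid),
        fold_aucs=np.asarray(aucs),
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        sensitivity_mean=float(np.mean(sens)),
        specificity_mean=float(np.mean(spec)),
        fold_assignments=folds,
    )
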