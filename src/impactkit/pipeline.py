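"""End-to-end workflows tying the modules together.

These are the library-level commands behind the CLI: feature extraction
over a recording set, IR model fitting, ground-truth construction,
classifier training with (or bypassing) forward selection, whole-event
classification, and feature screening.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import (ClassifierConfig, EvaluationReport, TrainedClassifier,
                       loocv_decision_values, roc_pr_curves,
                       sequential_forward_selection, train_rbf_svm)
from .groundtruth import IRPlacementModel, classify_placement, extract_features, fit_ir_threshold
from .io import FeatureTable, Recording, SensorCalibration
from .neck import NeckModelParams
from .preprocess import preprocess_recording
from .registry import FEATURE_NAMES
from .stats import screen_features

logger = logging.getLogger(__name__)


def _neck_params(calib: SensorCalibration,
                 neck_params: NeckModelParams | None) -> NeckModelParams:
    return neck_params or NeckModelParams(lever_arm=calib.cog_lever_arm)


def extract_features_cmd(recordings: list[Recording], calib: SensorCalibration,
                         neck_params: NeckModelParams | None = None,
                         ) -> tuple[FeatureTable, list[str]]:
    """One 411-feature row per recording; failures are skipped and reported.

    Returns (table, ids of recordings that failed extraction).  At this
    stage rows are only flagged, never filtered.
    """
    params = _neck_params(calib, neck_params)
    rows, index, failed = [], [], []
    for rec in recordings:
        try:
            sig = preprocess_recording(rec, calib)
            rows.append(extract_features(sig, params))
            index.append(rec.recording_id)
        except Exception:
            logger.exception("feature extraction failed for %s", rec.recording_id)
            failed.append(rec.recording_id)
    feats = pd.DataFrame(rows, index=index) if rows else \
        pd.DataFrame(np.empty((0, len(FEATURE_NAMES))), columns=list(FEATURE_NAMES))
    return FeatureTable.from_features(feats), failed


def fit_ir_cmd(recordings: list[Recording], seed: int = 0) -> IRPlacementModel:
    """Fit the per-subject-event infrared placement model."""
    return fit_ir_threshold([r.ir_reading for r in recordings], seed=seed)


def train_cmd(dataset: FeatureTable, cfg: ClassifierConfig | None = None,
              feature_list: list[str] | None = None,
              ) -> tuple[TrainedClassifier, EvaluationReport, list[float]]:
    """Forward selection (unless a feature list is supplied) + final fit.

    Returns the model trained on all labeled rows over the selected
    features, the LOOCV evaluation report on those features, and the
    selection cost trace (empty when selection was bypassed).
    """
    cfg = cfg or ClassifierConfig()
    labeled = dataset.data[dataset.labels.isin(["impact", "nonimpact"])]
    if labeled["label"].nunique() < 2:
        raise ValueError("training requires both impact and nonimpact rows")
    X_full = labeled[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = labeled["label"].to_numpy()

    if feature_list is not None:
        unknown = [f for f in feature_list if f not in FEATURE_NAMES]
        if unknown:
            raise KeyError(f"features not in registry: {unknown}")
        names = list(feature_list)
        trace: list[float] = []
    else:
        cols, trace = sequential_forward_selection(
            X_full, y, cfg, feature_names=list(FEATURE_NAMES))
        names = [FEATURE_NAMES[j] for j in cols]
    X = labeled[names].to_numpy(dtype=float)
    model = train_rbf_svm(X, y, cfg, feature_names=names)
    values, _ = loocv_decision_values(X, y, cfg)
    report = roc_pr_curves(values, y)
    return model, report, trace


def classify_cmd(recordings: list[Recording], ir_model: IRPlacementModel,
                 model: TrainedClassifier, calib: SensorCalibration,
                 neck_params: NeckModelParams | None = None) -> pd.DataFrame:
    """Two-stage disposition of every recording in an event.

    IR rejection runs first (off-teeth recordings never reach the SVM);
    the rest are classified impact/nonimpact; extraction failures get the
    'error' disposition.  Returns a timeline DataFrame (recording_id,
    trigger_ts, disposition, decision_value) sorted by timestamp.
    """
    params = _neck_params(calib, neck_params)
    rows = []
    for rec in recordings:
        if classify_placement(rec, ir_model) == "off_teeth":
            rows.append((rec.recording_id, rec.trigger_timestamp,
                         "ir_rejected", np.nan))
            continue
        try:
            sig = preprocess_recording(rec, calib)
            vec = extract_features(sig, params)
        except Exception:
            logger.exception("classification failed for %s", rec.recording_id)
            rows.append((rec.recording_id, rec.trigger_timestamp, "error", np.nan))
            continue
        value = float(model.decision_values(
            vec[model.feature_names].to_numpy()[None, :])[0])
        disposition = "impact" if value >= model.threshold else "nonimpact"
        rows.append((rec.recording_id, rec.trigger_timestamp, disposition, value))
    out = pd.DataFrame(rows, columns=["recording_id", "trigger_ts",
                                      "disposition", "decision_value"])
    return out.sort_values(["trigger_ts", "recording_id"]).reset_index(drop=True)


def screen_cmd(dataset: FeatureTable) -> pd.DataFrame:
    """Rank-sum + Bonferroni screen of every feature between the classes."""
    feats = dataset.features
    imp = feats[dataset.labels == "impact"]
    non = feats[dataset.labels == "nonimpact"]
    if imp.empty or non.empty:
        raise ValueError("screening requires both impact and nonimpact rows")
    return screen_features(imp, non)
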