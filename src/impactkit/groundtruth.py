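"""Infrared placement thresholding and labeled-dataset construction.

The mouthguard's infrared proximity channel reads high when the tray sits
on the upper dentition and low when it is off-teeth; a subject-event's
readings are typically bimodal.  A two-component 1-D Gaussian mixture is
fitted per subject-event and the decision threshold is the weighted-density
crossing between the two component means.

Ground-truth labels are built by cross-referencing recordings against
video activity intervals under strict conjunctive rules:

* impact: on-teeth, matched to a helmet-contact interval dilated by +/-2 s
  (mouthguard clock resolution is 1 s and synchronisation adds error),
  kinematic direction consistent with the video-observed impact direction,
  and not rejected as high-frequency noise;
* nonimpact: on-teeth and strictly inside a no-contact or idle interval,
  with no contact-like or view-limited interval matching under dilation;
* everything else is excluded (never silently re-labeled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .features import periodogram_psd, psd_features, time_domain_features, wavelet_features, assemble_feature_vector
from .io import FeatureTable, Recording, SensorCalibration, VideoLabel
from .neck import NeckModelParams, model_feature_block
from .preprocess import AnatomicalSignals, preprocess_recording

logger = logging.getLogger(__name__)

MATCH_WINDOW_S = 2.0
#: half-angle of the 90-degree direction cones
CONE_HALF_ANGLE_DEG = 45.0

#: video direction -> expected head-acceleration sector axis (AP, LR, IS).
#: Acceleration points away from the impacted surface: a frontal blow pushes
#: the head posteriorly (-AP); a blow to the player's left pushes it
#: rightward (-LR, with LR = +left); a top blow pushes it inferiorly (-IS).
DIRECTION_AXES = {
    "frontal": np.array([-1.0, 0.0, 0.0]),
    "rear": np.array([1.0, 0.0, 0.0]),
    "left": np.array([0.0, -1.0, 0.0]),
    "right": np.array([0.0, 1.0, 0.0]),
    "top": np.array([0.0, 0.0, -1.0]),
}

#: precedence when a recording matches overlapping categories
CATEGORY_PRECEDENCE = ("helmet_contact", "no_view", "obstructed", "body_contact",
                      "no_contact", "idle")


class InsufficientDataError(ValueError):
    pass


@dataclass
class IRPlacementModel:
    """Dual-Gaussian fit of a subject-event's infrared readings."""

    low_mean: float
    low_sd: float
    low_weight: float
    high_mean: float
    high_sd: float
    high_weight: float
    threshold: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "low_mean", "low_sd", "low_weight", "high_mean", "high_sd",
            "high_weight", "threshold", "degenerate")}

    @classmethod
    def from_dict(cls, d: dict) -> "IRPlacementModel":
        return cls(**d)


def fit_ir_threshold(readings, seed: int = 0) -> IRPlacementModel:
    """Fit a two-component Gaussian mixture and locate the density crossing.

    EM is initialised deterministically at the 25th/75th percentiles of the
    readings.  The threshold solves
    w_low N(x; mu_low, sd_low) = w_high N(x; mu_high, sd_high) on
    (mu_low, mu_high).  When the means are closer than the pooled sd the
    fit is flagged degenerate and the threshold falls back to the midpoint
    of the means.
    """
    x = np.asarray(readings, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise InsufficientDataError(
            f"need >= 10 infrared readings to fit a placement model, got {len(x)}")
    q25, q75 = np.percentile(x, [25, 75])
    gm = GaussianMixture(
        n_components=2, covariance_type="diag", n_init=1,
        means_init=[[q25], [q75]], weights_init=[0.5, 0.5],
        random_state=seed, reg_covar=1e-6,
    ).fit(x)
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    pooled_sd = math.sqrt(0.5 * (sds[0] ** 2 + sds[1] ** 2))
    # EM splits even a unimodal sample into components ~1.9 pooled sd
    # apart; genuinely bimodal on/off-teeth readings sit far wider
    degenerate = (means[1] - means[0]) < 2.5 * pooled_sd

    if degenerate:
        threshold = 0.5 * (means[0] + means[1])
    else:
        def log_density_gap(v: float) -> float:
            lo = math.log(weights[0] / sds[0]) - 0.5 * ((v - means[0]) / sds[0]) ** 2
            hi = math.log(weights[1] / sds[1]) - 0.5 * ((v - means[1]) / sds[1]) ** 2
            return lo - hi

        a, b = means[0], means[1]
        if log_density_gap(a) > 0 > log_density_gap(b):
            threshold = float(brentq(log_density_gap, a, b, xtol=1e-12))
        else:   # crossing not bracketed between the means
            degenerate = True
            threshold = 0.5 * (means[0] + means[1])
    return IRPlacementModel(
        low_mean=float(means[0]), low_sd=float(sds[0]), low_weight=float(weights[0]),
        high_mean=float(means[1]), high_sd=float(sds[1]), high_weight=float(weights[1]),
        threshold=float(threshold), degenerate=bool(degenerate))


def classify_placement(rec: Recording, model: IRPlacementModel) -> str:
    """'on_teeth' iff the reading is at or above the threshold (inclusive)."""
    return "on_teeth" if rec.ir_reading >= model.threshold else "off_teeth"


def match_labels(rec_ts: float, labels: list[VideoLabel],
                 window: float = MATCH_WINDOW_S) -> list[VideoLabel]:
    """Video labels whose interval, dilated by +/-window, contains rec_ts."""
    return [lbl for lbl in labels
            if lbl.start - window <= rec_ts <= lbl.end + window]


def direction_consistent(sig: AnatomicalSignals, direction: str) -> bool:
    """Does the kinematic direction match the video-observed impact side?

    True iff the peak linear-acceleration vector OR the end-of-window
    velocity-change vector lies inside the 90-degree cone about the
    sector axis assigned to the video direction.
    """
    if direction not in DIRECTION_AXES:
        raise ValueError(f"direction must be one of {sorted(DIRECTION_AXES)}, "
                         f"got {direction!r}")
    axis = DIRECTION_AXES[direction]
    cos_limit = math.cos(math.radians(CONE_HALF_ANGLE_DEG))
    peak_acc = sig.lin_acc[:, int(np.argmax(sig.lin_acc_mag))]
    delta_v = sig.lin_vel[:, -1]
    for vec in (peak_acc, delta_v):
        norm = np.linalg.norm(vec)
        if norm > 0 and float(vec @ axis) / norm >= cos_limit:
            return True
    return False


def hf_noise_reject(sig: AnatomicalSignals) -> bool:
    """Reject recordings dominated by >200 Hz power (electronics noise).

    Compares periodogram power of the linear-acceleration magnitude summed
    over bins above 200 Hz against the sum at and below 200 Hz.  The DC bin
    is excluded: the magnitude series is nonnegative, so its mean is an
    offset, not band content, and counting it would make the rule vacuous.
    """
    freqs, psd = periodogram_psd(sig.lin_acc_mag)
    high = psd[freqs > 200.0].sum()
    low = psd[(freqs > 0.0) & (freqs <= 200.0)].sum()
    return bool(high > low)


def extract_features(sig: AnatomicalSignals,
                     neck_params: NeckModelParams | None = None) -> pd.Series:
    """Full 411-slot canonical feature vector for one preprocessed recording."""
    return assemble_feature_vector(
        time_domain_features(sig), psd_features(sig), wavelet_features(sig),
        model_feature_block(sig, neck_params))


def _resolve_category(matched: list[VideoLabel]) -> VideoLabel | None:
    for cat in CATEGORY_PRECEDENCE:
        for lbl in matched:
            if lbl.category == cat:
                return lbl
    return None


def build_ground_truth(recs: list[Recording], labels: list[VideoLabel],
                       calib: SensorCalibration,
                       ir_model: IRPlacementModel,
                       neck_params: NeckModelParams | None = None,
                       window: float = MATCH_WINDOW_S) -> FeatureTable:
    """Construct the labeled impact/nonimpact dataset.

    Selection rules are conjunctive: failing any impact rule excludes the
    recording entirely; it is never reassigned to the nonimpact class.
    Features are extracted only for included rows.
    """
    labels = sorted(labels, key=lambda lbl: (lbl.start, lbl.end))
    rows, index = [], []
    meta = {"label": [], "ir_pass": [], "direction_pass": [], "hf_pass": []}
    n_excluded = 0
    for rec in recs:
        ir_pass = classify_placement(rec, ir_model) == "on_teeth"
        matched = match_labels(rec.trigger_timestamp, labels, window)
        top = _resolve_category(matched)

        if top is not None and top.category == "helmet_contact":
            if not ir_pass:
                n_excluded += 1
                continue
            sig = preprocess_recording(rec, calib)
            dir_pass = (top.direction == "none"
                        or direction_consistent(sig, top.direction))
            hf_pass = not hf_noise_reject(sig)
            if not (dir_pass and hf_pass):
                n_excluded += 1
                continue
            label = "impact"
        else:
            inside_quiet = any(
                lbl.start < rec.trigger_timestamp < lbl.end
                for lbl in labels if lbl.category in ("no_contact", "idle"))
            contact_like = any(
                lbl.category in ("helmet_contact", "body_contact", "obstructed",
                                 "no_view") for lbl in matched)
            if not (ir_pass and inside_quiet and not contact_like):
                n_excluded += 1
                continue
            sig = preprocess_recording(rec, calib)
            dir_pass = hf_pass = True
            label = "nonimpact"

        rows.append(extract_features(sig, neck_params))
        index.append(rec.recording_id)
        meta["label"].append(label)
        meta["ir_pass"].append(ir_pass)
        meta["direction_pass"].append(dir_pass)
        meta["hf_pass"].append(hf_pass)

    feats = pd.DataFrame(rows, index=index)
    if feats.empty:
        logger.warning("ground-truth construction produced an empty dataset "
                       "(%d recordings excluded)", n_excluded)
        from .registry import FEATURE_NAMES
        feats = pd.DataFrame(np.empty((0, len(FEATURE_NAMES))),
                             columns=list(FEATURE_NAMES))
    table = FeatureTable.from_features(
        feats, labels=pd.Series(meta["label"], index=index, dtype=object),
        flags=pd.DataFrame({k: pd.Series(meta[k], index=index)
                            for k in ("ir_pass", "direction_pass", "hf_pass")}))
    logger.info("ground truth: %d impacts, %d nonimpacts, %d excluded",
                sum(1 for v in meta["label"] if v == "impact"),
                sum(1 for v in meta["label"] if v == "nonimpact"), n_excluded)
    return table
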