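"""Data model and file I/O.

Core record types for triggered mouthguard recordings, video activity
labels, sensor calibration, and extracted feature tables, together with
plain-text (CSV) and HDF5 readers/writers.

A triggered recording is a 100 ms window sampled at 1000 Hz (10 ms
pre-trigger, 90 ms post-trigger, 10 g trigger): triaxial linear
acceleration in g, triaxial angular velocity in rad/s, one infrared
proximity reading, and a trigger timestamp with 1 s resolution.

Recording CSV schema (long): one row per sample with columns
``recording_id, subject_event_id, trigger_ts, t_ms, ax_g, ay_g, az_g,
wx_rps, wy_rps, wz_rps, ir``.  The HDF5 layout stores one group per
recording with ``lin_acc`` (3x100) and ``ang_vel`` (3x100) datasets and
``trigger_ts`` / ``ir_reading`` / ``subject_event_id`` attributes.

Feature-table CSV carries a registry-version comment line; reads refuse a
version or column mismatch rather than coercing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .registry import FEATURE_NAMES, REGISTRY_VERSION, RegistryError, registry_hash

N_SAMPLES = 100
FS_HZ = 1000.0
DT_S = 1.0 / FS_HZ
PRETRIGGER_SAMPLES = 10

GRAVITY = 9.80665  # m/s^2 per g

CATEGORIES = ("helmet_contact", "body_contact", "no_contact", "idle", "obstructed", "no_view")
DIRECTIONS = ("frontal", "left", "right", "rear", "top", "none")

META_COLUMNS = ("label", "ir_pass", "direction_pass", "hf_pass")


class SchemaError(ValueError):
    """Input file violates the documented recording/label schema."""


class CalibrationError(ValueError):
    """Sensor calibration is not a proper rotation / has bad parameters."""


@dataclass
class Recording:
    """One triggered 100 ms 6-DOF window plus its infrared reading."""

    recording_id: str
    subject_event_id: str
    trigger_timestamp: int           # seconds, 1 s resolution
    lin_acc_device: np.ndarray       # (3, 100) in g, device frame
    ang_vel_device: np.ndarray       # (3, 100) in rad/s, device frame
    ir_reading: float                # device units

    def __post_init__(self) -> None:
        self.lin_acc_device = np.asarray(self.lin_acc_device, dtype=float)
        self.ang_vel_device = np.asarray(self.ang_vel_device, dtype=float)
        self.validate()

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds relative to the trigger (10 ms pre-trigger)."""
        return (np.arange(N_SAMPLES) - PRETRIGGER_SAMPLES) * DT_S

    def validate(self) -> None:
        for name, arr in (("lin_acc_device", self.lin_acc_device),
                          ("ang_vel_device", self.ang_vel_device)):
            if arr.shape != (3, N_SAMPLES):
                raise SchemaError(
                    f"recording {self.recording_id!r}: {name} has shape "
                    f"{arr.shape}, expected (3, {N_SAMPLES})"
                )
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"recording {self.recording_id!r}: non-finite {name}")
        if not np.isfinite(self.ir_reading):
            raise SchemaError(f"recording {self.recording_id!r}: non-finite ir_reading")
        self.trigger_timestamp = int(self.trigger_timestamp)


@dataclass
class VideoLabel:
    """One video activity interval: category plus (for helmet contact) direction."""

    start: float                     # seconds
    end: float                       # seconds
    category: str
    direction: str = "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"unknown video label category {self.category!r}; "
                f"allowed: {', '.join(CATEGORIES)}"
            )
        if self.direction not in DIRECTIONS:
            raise SchemaError(
                f"unknown impact direction {self.direction!r}; "
                f"allowed: {', '.join(DIRECTIONS)}"
            )
        if self.start > self.end:
            raise SchemaError(f"video label start {self.start} > end {self.end}")
        if self.direction != "none" and self.category != "helmet_contact":
            raise SchemaError("direction is only meaningful for helmet_contact labels")


@dataclass
class SensorCalibration:
    """Per-subject device-to-anatomical rotation and sensor bandwidths."""

    device_to_anatomical: np.ndarray = field(
        default_factory=lambda: np.eye(3))   # 3x3 rotation
    accel_cutoff: float = 500.0              # Hz
    gyro_cutoff: float = 184.0               # Hz
    cog_lever_arm: np.ndarray = field(
        default_factory=lambda: np.zeros(3))  # m, sensor origin -> head CoG

    def __post_init__(self) -> None:
        self.device_to_anatomical = np.asarray(self.device_to_anatomical, dtype=float)
        self.cog_lever_arm = np.asarray(self.cog_lever_arm, dtype=float)
        R = self.device_to_anatomical
        if R.shape != (3, 3) or np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8 \
                or np.linalg.det(R) < 0:
            raise CalibrationError("device_to_anatomical must be a proper rotation matrix")
        if self.accel_cutoff <= 0 or self.gyro_cutoff <= 0:
            raise CalibrationError("filter cutoffs must be positive")
        if self.cog_lever_arm.shape != (3,):
            raise CalibrationError("cog_lever_arm must be a 3-vector (metres)")


@dataclass
class FeatureTable:
    """Rows of recordings x the 411 canonical features, plus label/provenance.

    ``data`` is indexed by recording_id and holds the meta columns
    (``label`` in {impact, nonimpact} or empty, boolean ``ir_pass`` /
    ``direction_pass`` / ``hf_pass``) followed by the 411 feature columns
    in registry order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise RegistryError(f"duplicate feature-table columns: {dupes}")
        expected = list(META_COLUMNS) + list(FEATURE_NAMES)
        if cols != expected:
            raise RegistryError(
                f"feature table has {len(cols)} columns; expected the "
                f"{len(expected)} canonical columns of {REGISTRY_VERSION}"
            )
        feats = self.data[list(FEATURE_NAMES)].to_numpy(dtype=float)
        if feats.size and not np.all(np.isfinite(feats)):
            bad = self.data.index[~np.isfinite(feats).all(axis=1)].tolist()
            raise RegistryError(f"non-finite feature values for rows {bad}")

    @classmethod
    def from_features(cls, features: pd.DataFrame,
                      labels: pd.Series | None = None,
                      flags: pd.DataFrame | None = None) -> "FeatureTable":
        meta = pd.DataFrame(index=features.index)
        meta["label"] = "" if labels is None else labels
        for flag in META_COLUMNS[1:]:
            meta[flag] = True if flags is None else flags[flag]
        df = pd.concat([meta, features.reindex(columns=list(FEATURE_NAMES))], axis=1)
        return cls(df)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[list(FEATURE_NAMES)]

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# recordings

_CSV_COLUMNS = ["recording_id", "subject_event_id", "trigger_ts", "t_ms",
                "ax_g", "ay_g", "az_g", "wx_rps", "wy_rps", "wz_rps", "ir"]


def _sorted(recs: list[Recording]) -> list[Recording]:
    return sorted(recs, key=lambda r: (r.trigger_timestamp, r.recording_id))


def read_recordings(path: str | Path, schema: str = "auto") -> list[Recording]:
    """Read recordings from CSV or HDF5, ordered by (trigger_ts, id)."""
    path = Path(path)
    if schema == "auto":
        schema = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if schema == "hdf5":
        return _read_recordings_hdf5(path)
    if schema != "csv":
        raise ValueError(f"unknown recording schema {schema!r}")

    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"recording CSV missing columns: {missing}")
    recs = []
    for rid, grp in df.groupby("recording_id", sort=False):
        if len(grp) != N_SAMPLES:
            raise SchemaError(
                f"recording {rid!r} has {len(grp)} samples, expected {N_SAMPLES}")
        t = grp["t_ms"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise SchemaError(f"recording {rid!r}: t_ms not strictly increasing")
        recs.append(Recording(
            recording_id=str(rid),
            subject_event_id=str(grp["subject_event_id"].iloc[0]),
            trigger_timestamp=int(grp["trigger_ts"].iloc[0]),
            lin_acc_device=grp[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float).T,
            ang_vel_device=grp[["wx_rps", "wy_rps", "wz_rps"]].to_numpy(dtype=float).T,
            ir_reading=float(grp["ir"].iloc[0]),
        ))
    return _sorted(recs)


def write_recordings(recs: list[Recording], path: str | Path,
                     schema: str = "auto") -> None:
    path = Path(path)
    if schema == "auto":
        schema = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if schema == "hdf5":
        _write_recordings_hdf5(recs, path)
        return
    if schema != "csv":
        raise ValueError(f"unknown recording schema {schema!r}")
    frames = []
    t_ms = (np.arange(N_SAMPLES) - PRETRIGGER_SAMPLES) * 1.0
    for r in _sorted(recs):
        frames.append(pd.DataFrame({
            "recording_id": r.recording_id,
            "subject_event_id": r.subject_event_id,
            "trigger_ts": r.trigger_timestamp,
            "t_ms": t_ms,
            "ax_g": r.lin_acc_device[0], "ay_g": r.lin_acc_device[1],
            "az_g": r.lin_acc_device[2],
            "wx_rps": r.ang_vel_device[0], "wy_rps": r.ang_vel_device[1],
            "wz_rps": r.ang_vel_device[2],
            "ir": r.ir_reading,
        }))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=_CSV_COLUMNS))
    out.to_csv(path, index=False)


def _read_recordings_hdf5(path: Path) -> list[Recording]:
    recs = []
    with h5py.File(path, "r") as f:
        for rid in f:
            g = f[rid]
            recs.append(Recording(
                recording_id=rid,
                subject_event_id=str(g.attrs["subject_event_id"]),
                trigger_timestamp=int(g.attrs["trigger_ts"]),
                lin_acc_device=np.asarray(g["lin_acc"]),
                ang_vel_device=np.asarray(g["ang_vel"]),
                ir_reading=float(g.attrs["ir_reading"]),
            ))
    return _sorted(recs)


def _write_recordings_hdf5(recs: list[Recording], path: Path) -> None:
    with h5py.File(path, "w") as f:
        for r in _sorted(recs):
            g = f.create_group(r.recording_id)
            g.create_dataset("lin_acc", data=r.lin_acc_device)
            g.create_dataset("ang_vel", data=r.ang_vel_device)
            g.attrs["subject_event_id"] = r.subject_event_id
            g.attrs["trigger_ts"] = r.trigger_timestamp
            g.attrs["ir_reading"] = r.ir_reading


# ---------------------------------------------------------------------------
# video labels

def read_video_labels(path: str | Path) -> list[VideoLabel]:
    """Read video-label CSV (start_s, end_s, category, direction), sorted by start."""
    df = pd.read_csv(path)
    missing = [c for c in ("start_s", "end_s", "category") if c not in df.columns]
    if missing:
        raise SchemaError(f"video label CSV missing columns: {missing}")
    labels = []
    for _, row in df.iterrows():
        direction = row.get("direction", "none")
        if pd.isna(direction) or direction == "":
            direction = "none"
        labels.append(VideoLabel(float(row["start_s"]), float(row["end_s"]),
                                 str(row["category"]), str(direction)))
    return sorted(labels, key=lambda lbl: (lbl.start, lbl.end))


def write_video_labels(labels: list[VideoLabel], path: str | Path) -> None:
    pd.DataFrame({
        "start_s": [lbl.start for lbl in labels],
        "end_s": [lbl.end for lbl in labels],
        "category": [lbl.category for lbl in labels],
        "direction": [lbl.direction for lbl in labels],
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature tables

_REGISTRY_COMMENT = "# registry"


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with a registry-version header line."""
    table.validate()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_REGISTRY_COMMENT}={REGISTRY_VERSION} hash={registry_hash()}\n")
        table.data.to_csv(fh, index_label="recording_id", float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        expected = f"{_REGISTRY_COMMENT}={REGISTRY_VERSION} hash={registry_hash()}"
        if header != expected:
            raise RegistryError(
                f"feature table registry header {header!r} does not match "
                f"{REGISTRY_VERSION}; refusing to coerce")
        df = pd.read_csv(fh, index_col="recording_id",
                         float_precision="round_trip")
    df["label"] = df["label"].fillna("").astype(str)
    for flag in META_COLUMNS[1:]:
        df[flag] = df[flag].astype(bool)
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# small JSON helpers (trained models, IR placement models)

def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
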