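"""Recording / feature / event CSV readers and writers.

One recording CSV per trial: a ``time_s`` column followed by
``<location>_<gyr|acc>_<x|y|z>`` for the eight sensor locations (49 columns
total), times in seconds, floats with 6 decimals, UTF-8, header mandatory.
Trial metadata lives in a YAML sidecar next to the CSV
(``<stem>.meta.yaml``) with keys subject_id, group, condition, test, fs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CorruptFileError, SchemaError
from .preprocess import (
    LOCATIONS,
    KinematicRecording,
    SensorStream,
    TrialMeta,
)
from .synth import GroundTruth

__all__ = [
    "recording_columns",
    "read_recording",
    "write_recording",
    "write_ground_truth",
    "read_feature_table",
    "write_feature_table",
    "RunManifest",
    "ManifestEntry",
]

_AXES = ("x", "y", "z")
_KINDS = ("gyr", "acc")
_META_KEYS = ("subject_id", "group", "condition", "test", "fs")
_TIME_JITTER_S = 1e-6


def recording_columns() -> list[str]:
    """The declared column order of a recording CSV."""
    cols = ["time_s"]
    for loc in LOCATIONS:
        for kind in _KINDS:
            for ax in _AXES:
                cols.append(f"{loc}_{kind}_{ax}")
    return cols


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix("").with_suffix(".meta.yaml")


def write_recording(rec: KinematicRecording, path: str | Path) -> Path:
    """Write a recording CSV plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    n = rec.n_samples
    data = {"time_s": np.arange(n) / rec.fs}
    for loc in LOCATIONS:
        s = rec.streams[loc]
        for kind, arr in (("gyr", s.ang_vel), ("acc", s.lin_acc)):
            for i, ax in enumerate(_AXES):
                data[f"{loc}_{kind}_{ax}"] = arr[:, i]
    pd.DataFrame(data, columns=recording_columns()).to_csv(
        path, index=False, float_format="%.6f"
    )
    meta = {
        "subject_id": rec.meta.subject_id,
        "group": rec.meta.group,
        "condition": rec.meta.condition,
        "test": rec.meta.test,
        "fs": float(rec.fs),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True), encoding="utf-8")
    return path


def read_recording(path: str | Path) -> KinematicRecording:
    """Read a recording CSV (+ YAML sidecar) back into a recording.

    Raises :class:`~mobiseg.errors.SchemaError` for a missing column or
    sidecar key and :class:`~mobiseg.errors.CorruptFileError` for a
    non-monotone or non-uniform time column (jitter above 1 microsecond).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in recording_columns() if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"metadata sidecar not found: {sidecar.name}")
    meta_raw = yaml.safe_load(sidecar.read_text(encoding="utf-8"))
    if not isinstance(meta_raw, dict):
        raise SchemaError(f"{sidecar.name}: sidecar must be a mapping")
    missing_keys = [k for k in _META_KEYS if k not in meta_raw]
    if missing_keys:
        raise SchemaError(f"{sidecar.name}: missing keys {missing_keys}")

    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or (dt <= 0).any():
        raise CorruptFileError(f"{path.name}: time column is not strictly increasing")
    fs_sidecar = float(meta_raw["fs"])
    expected = np.arange(len(t)) / fs_sidecar
    if np.max(np.abs(t - expected)) > _TIME_JITTER_S + 1e-12:
        raise CorruptFileError(
            f"{path.name}: time column inconsistent with fs={fs_sidecar} Hz "
            f"(jitter above {_TIME_JITTER_S} s)"
        )

    meta = TrialMeta(
        subject_id=str(meta_raw["subject_id"]),
        group=str(meta_raw["group"]),
        condition=str(meta_raw["condition"]),
        test=str(meta_raw["test"]),
    )
    streams = {}
    for loc in LOCATIONS:
        gyr = df[[f"{loc}_gyr_{ax}" for ax in _AXES]].to_numpy(dtype=float)
        acc = df[[f"{loc}_acc_{ax}" for ax in _AXES]].to_numpy(dtype=float)
        streams[loc] = SensorStream(location=loc, ang_vel=gyr, lin_acc=acc, fs=fs_sidecar)
    return KinematicRecording(streams=streams, meta=meta)


def write_ground_truth(truths: dict[str, GroundTruth], path: str | Path) -> Path:
    """Write ground truths of one or more trials to a long-format CSV.

    Columns: trial, kind (event|feature), name, index, value.
    """
    rows = []
    for trial, gt in truths.items():
        for fam, times in gt.events.items():
            for i, tval in enumerate(times):
                rows.append(
                    {"trial": trial, "kind": "event", "name": fam, "index": i, "value": tval}
                )
        for name, val in gt.features.items():
            rows.append(
                {"trial": trial, "kind": "feature", "name": name, "index": 0, "value": val}
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
    return path


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6f")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["subject_id", "group", "condition", "feature", "value"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ManifestEntry:
    """Per-trial outcome of a pipeline run; failures are never dropped."""

    trial: str
    status: str  # "ok" | "segmentation-failed" | "error"
    message: str = ""


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: config hash, version, per-trial status."""

    config_hash: str
    version: str
    entries: list[ManifestEntry] = dataclasses.field(default_factory=list)
    timestamp: str = ""

    def add(self, trial: str, status: str, message: str = "") -> None:
        self.entries.append(ManifestEntry(trial=trial, status=status, message=message))

    @property
    def n_ok(self) -> int:
        return sum(1 for e in self.entries if e.status == "ok")

    @property
    def n_failed(self) -> int:
        return len(self.entries) - self.n_ok

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "timestamp": self.timestamp,
            "n_trials": len(self.entries),
            "n_ok": self.n_ok,
            "n_failed": self.n_failed,
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")
        return path
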