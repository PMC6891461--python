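"""Plain-text I/O: trial CSV + JSON sidecar, feature tables, reports.

Trials are stored as a wide CSV (time_s, one column per angle channel and
per position axis) plus a JSON sidecar holding sampling rate, group label,
ground truth and reference-channel offsets. Floats are written with 17
significant digits so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (TrialRecording, TrialTruth, ANGLE_CHANNELS,
                        POSITION_KEYS)

__all__ = [
    "SchemaError",
    "write_trial_csv",
    "read_trial_csv",
    "write_feature_table",
    "read_feature_table",
    "write_json_report",
]

_FLOAT_FMT = "%.17g"
_AXES = ("x", "y", "z")


class SchemaError(ValueError):
    """A required column or sidecar field is missing or malformed."""


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trial_csv(trial: TrialRecording, path: str | Path) -> Path:
    """Write one trial as wide CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {"time_s": trial.time}
    for name in ANGLE_CHANNELS:
        data[name] = trial.channels[name]
    if trial.reference_channels is not None:
        for name in ANGLE_CHANNELS:
            data[f"ref_{name}"] = trial.reference_channels[name]
    for key in POSITION_KEYS:
        pos = trial.positions[key]
        for j, ax in enumerate(_AXES):
            data[f"{key}_{ax}"] = pos[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)

    sidecar = {
        "subject_id": trial.subject_id,
        "group": trial.group,
        "operated_side": trial.operated_side,
        "fs": trial.fs,
        "ref_offsets": trial.ref_offsets,
        "truth": trial.truth.to_jsonable() if trial.truth else None,
        "meta": _jsonable(trial.meta),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_trial_csv(path: str | Path) -> TrialRecording:
    """Reconstruct a trial from its CSV + sidecar (column order agnostic)."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise SchemaError(f"missing sidecar {sidecar_file.name}")
    with open(sidecar_file) as fh:
        sidecar = json.load(fh)
    for field in ("subject_id", "group", "operated_side", "fs"):
        if field not in sidecar:
            raise SchemaError(f"sidecar missing field {field!r}")

    def col(name: str) -> np.ndarray:
        if name not in df.columns:
            raise SchemaError(f"missing required column {name!r}")
        return df[name].to_numpy(float)

    channels = {name: col(name) for name in ANGLE_CHANNELS}
    reference = None
    if f"ref_{ANGLE_CHANNELS[0]}" in df.columns:
        reference = {name: col(f"ref_{name}") for name in ANGLE_CHANNELS}
    positions = {
        key: np.column_stack([col(f"{key}_{ax}") for ax in _AXES])
        for key in POSITION_KEYS
    }
    truth = (TrialTruth.from_jsonable(sidecar["truth"])
             if sidecar.get("truth") else None)
    return TrialRecording(
        subject_id=sidecar["subject_id"], group=sidecar["group"],
        operated_side=sidecar["operated_side"], fs=float(sidecar["fs"]),
        channels=channels, positions=positions,
        reference_channels=reference,
        ref_offsets=sidecar.get("ref_offsets"),
        truth=truth, meta=sidecar.get("meta") or {})


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise SchemaError("missing required column 'label'")
    return df


def write_json_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return path
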