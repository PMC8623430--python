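"""Reading and writing tracker tables, feature tables and cohort manifests.

Tracker tables are the CSV export of the marker-tracking step: one row
per frame with columns ``frame,spot,x,y`` (header optional, detected
automatically).  Feature tables are CSV with identifier columns, the 14
spectral predictors in fixed order, and the class label; round-trips are
lossless to 15+ significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingFramesError, SchemaError
from .recording import PHASES, TrajectoryRecording
from .spectral_features import FEATURE_COLUMNS

__all__ = [
    "read_tracker_table",
    "write_tracker_table",
    "read_feature_table",
    "write_feature_table",
    "write_cohort",
    "read_cohort",
    "FEATURE_TABLE_COLUMNS",
]

TRACKER_COLUMNS = ("frame", "spot", "x", "y")
FEATURE_TABLE_COLUMNS = ("patient_id", "phase", "recording_id", *FEATURE_COLUMNS, "label")

#: Repr-exact float formatting used for all CSV output.
_FLOAT_FORMAT = "%.17g"


def _is_header(first_line: str) -> bool:
    token = first_line.split(",")[0].strip()
    try:
        float(token)
        return False
    except ValueError:
        return True


def read_tracker_table(
    path,
    sampling_rate: float,
    marker=None,
    patient_id: str = "",
    phase: str = "unknown",
    recording_id: str = "",
) -> TrajectoryRecording:
    """Read one marker trajectory from a tracker CSV.

    Rows carry (frame, marker id, x, y); they are sorted by frame and a
    single marker is selected.  If the file tracks more than one marker,
    ``marker`` must name the one to load.  Gaps in the frame index raise
    :class:`MissingFramesError` listing the missing frames.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise SchemaError(f"{path}: empty tracker table")
    header = 0 if _is_header(first) else None
    try:
        df = pd.read_csv(path, header=header, names=TRACKER_COLUMNS, dtype=float, usecols=range(4),
                         float_precision="round_trip")
    except ValueError as err:
        raise SchemaError(f"{path}: unparseable tracker table ({err})") from err

    markers = np.unique(df["spot"].to_numpy())
    if marker is None:
        if markers.size > 1:
            raise ValueError(
                f"{path}: {markers.size} markers present ({markers.tolist()}); "
                "pass `marker=` to select one"
            )
        marker = markers[0]
    df = df[df["spot"] == float(marker)]
    if df.empty:
        raise ValueError(f"{path}: no rows for marker {marker!r}")
    df = df.sort_values("frame", kind="stable")

    frames = df["frame"].to_numpy()
    if not np.allclose(frames, np.round(frames)):
        raise SchemaError(f"{path}: non-integer frame indices")
    frames = np.round(frames).astype(int)
    expected = np.arange(frames[0], frames[-1] + 1)
    if frames.size != expected.size or (frames != expected).any():
        missing = sorted(set(expected.tolist()) - set(frames.tolist()))
        raise MissingFramesError(missing)

    return TrajectoryRecording(
        patient_id=patient_id or path.stem,
        phase=phase if phase in PHASES else "unknown",
        sampling_rate=sampling_rate,
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        recording_id=recording_id or path.stem,
    )


def write_tracker_table(recording: TrajectoryRecording, path, marker: int = 0) -> None:
    """Write a recording as a headered tracker CSV (frame,spot,x,y)."""
    df = pd.DataFrame(
        {
            "frame": np.arange(recording.n_samples),
            "spot": marker,
            "x": recording.x,
            "y": recording.y,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table CSV (lossless float round-trip)."""
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    table.loc[:, list(FEATURE_TABLE_COLUMNS)].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV, validating the column schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    if tuple(df.columns) != FEATURE_TABLE_COLUMNS:
        raise SchemaError(
            f"{path}: feature table columns {list(df.columns)} do not match "
            f"the expected schema {list(FEATURE_TABLE_COLUMNS)}"
        )
    for col in FEATURE_COLUMNS:
        df[col] = df[col].astype(float)
    return df


def write_cohort(recordings: list[TrajectoryRecording], out_dir, extra_meta: dict | None = None) -> Path:
    """Write a recording set as tracker CSVs plus a JSON manifest.

    Returns the manifest path.  The manifest lists, per recording, the
    patient id, phase, sampling rate and relative file name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(recordings):
        name = f"{rec.recording_id or f'recording-{i:03d}'}.csv"
        write_tracker_table(rec, out_dir / name)
        entries.append(
            {
                "patient_id": rec.patient_id,
                "phase": rec.phase,
                "recording_id": rec.recording_id,
                "sampling_rate": rec.sampling_rate,
                "file": name,
            }
        )
    manifest = {"recordings": entries}
    if extra_meta:
        manifest["meta"] = extra_meta
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(manifest_path) -> list[TrajectoryRecording]:
    """Load every recording listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    recordings = []
    for entry in manifest["recordings"]:
        rec = read_tracker_table(
            manifest_path.parent / entry["file"],
            sampling_rate=entry["sampling_rate"],
            patient_id=entry["patient_id"],
            phase=entry["phase"],
            recording_id=entry["recording_id"],
        )
        recordings.append(rec)
    return recordings
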