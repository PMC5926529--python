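"""Plain-text table formats for every pipeline stage.

All tables are UTF-8 TSV/CSV with a header row and '.' decimal separator;
floats are written with enough digits for a lossless round trip.  Unknown
columns are preserved with a warning; missing required columns raise
:class:`SchemaError` naming them.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .trace_processing import GazeTrace

__all__ = [
    "SchemaError",
    "UnknownColumnWarning",
    "FLOAT_FORMAT",
    "read_table",
    "write_table",
    "write_traces",
    "read_traces",
]

FLOAT_FORMAT = "%.17g"

REQUIRED_COLUMNS = {
    "subjects": ["subject_id", "group", "icars"],
    "trials": [
        "subject_id",
        "trial_id",
        "fixation_onset_s",
        "target_onset_s",
        "target_direction",
        "eccentricity_deg",
        "target_offset_s",
    ],
    "traces": ["subject_id", "trial_id", "t_s", "x_deg", "y_deg"],
    "truth": ["subject_id", "trial_id", "label", "latency_ms"],
    "events": [
        "subject_id",
        "trial_id",
        "onset_s",
        "offset_s",
        "amplitude_deg",
        "angle_deg",
        "duration_ms",
        "vpeak",
        "vmean",
        "latency_ms",
    ],
    "classified": ["subject_id", "trial_id", "label", "exclusion_reason", "gain"],
}


class SchemaError(ValueError):
    pass


class UnknownColumnWarning(UserWarning):
    pass


def _check_schema(df: pd.DataFrame, kind: str, path) -> None:
    required = REQUIRED_COLUMNS.get(kind)
    if required is None:
        return
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(
            f"{path}: ignoring unknown columns {extra}", UnknownColumnWarning,
            stacklevel=3,
        )


def read_table(path: str | Path, kind: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if kind is not None:
        _check_schema(df, kind, path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)
    return path


def write_traces(traces: list[GazeTrace], path: str | Path) -> Path:
    """Long-format trace table: one row per sample."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                dict(
                    subject_id=tr.subject_id,
                    trial_id=tr.trial_id,
                    t_s=tr.t,
                    x_deg=tr.x,
                    y_deg=tr.y,
                )
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=REQUIRED_COLUMNS["traces"]
    )
    return write_table(df, path)


def read_traces(path: str | Path) -> list[GazeTrace]:
    """Rebuild per-trial traces; constructor validation rejects gapped time."""
    df = read_table(path, kind="traces")
    traces = []
    for (subject_id, trial_id), sub in df.groupby(
        ["subject_id", "trial_id"], sort=False
    ):
        traces.append(
            GazeTrace(
                t=sub["t_s"].to_numpy(float),
                x=sub["x_deg"].to_numpy(float),
                y=sub["y_deg"].to_numpy(float),
                subject_id=str(subject_id),
                trial_id=int(trial_id),
            )
        )
    return traces
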