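"""CSV readers/writers for the gaze, flow, label, and event schemas.

All schemas are plain UTF-8 CSV with a mandatory header and '.' decimal:

* gaze:   ``timestamp_s,x_px,y_px``
* flow:   ``timestamp_s,u_px_s,v_px_s``
* labels: ``timestamp_s,label``
* events: ``recording_id,start_s,end_s,label``

Timestamps are serialized with 9 decimal places so a write/read round trip
reproduces values to within float formatting.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .detectors import SampleLabels
from .events import Event, EventSequence
from .opticflow import FlowSeries
from .signal import GazeRecording

__all__ = ["SchemaError", "read_gaze", "write_gaze", "read_flow",
           "write_flow", "read_labels", "write_labels", "read_events",
           "write_events"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """A file does not conform to its documented CSV schema."""


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df.isna().any().any():
        row = int(np.argmax(df.isna().any(axis=1).to_numpy())) + 2
        raise SchemaError(f"{path}: missing value near row {row}")
    return df


def _check_monotone(path, t: np.ndarray, what: str = "timestamp_s") -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        # +3: header is line 1, data starts at line 2, offending value is
        # the second element of the first non-increasing pair
        raise SchemaError(f"{path}: non-monotone {what} at data row "
                          f"{int(bad[0]) + 3}")


def read_gaze(path, recording_id: str | None = None,
              condition: str = "unknown", rate_hz: float = 200.0,
              deg_per_px: float = 0.075) -> GazeRecording:
    df = _read_csv(path, ["timestamp_s", "x_px", "y_px"])
    t = df["timestamp_s"].to_numpy(float)
    _check_monotone(path, t)
    rid = recording_id if recording_id is not None else Path(path).stem
    return GazeRecording(t=t, x=df["x_px"].to_numpy(float),
                         y=df["y_px"].to_numpy(float), recording_id=rid,
                         condition=condition, rate_hz=rate_hz,
                         deg_per_px=deg_per_px)


def write_gaze(rec: GazeRecording, path) -> None:
    pd.DataFrame({"timestamp_s": rec.t, "x_px": rec.x, "y_px": rec.y}) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_flow(path) -> FlowSeries:
    df = _read_csv(path, ["timestamp_s", "u_px_s", "v_px_s"])
    t = df["timestamp_s"].to_numpy(float)
    _check_monotone(path, t)
    return FlowSeries(t=t, u=df["u_px_s"].to_numpy(float),
                      v=df["v_px_s"].to_numpy(float), source="file")


def write_flow(flow: FlowSeries, path) -> None:
    pd.DataFrame({"timestamp_s": flow.t, "u_px_s": flow.u,
                  "v_px_s": flow.v}) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_labels(path) -> SampleLabels:
    df = _read_csv(path, ["timestamp_s", "label"])
    t = df["timestamp_s"].to_numpy(float)
    _check_monotone(path, t)
    return SampleLabels(t=t, label=df["label"].to_numpy(object))


def write_labels(labels: SampleLabels, path) -> None:
    pd.DataFrame({"timestamp_s": labels.t, "label": labels.label}) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path) -> EventSequence:
    df = _read_csv(path, ["recording_id", "start_s", "end_s", "label"])
    if not df["start_s"].is_monotonic_increasing:
        log.warning("%s: event rows out of order; sorting on read", path)
        df = df.sort_values("start_s", kind="stable").reset_index(drop=True)
    events = []
    for i, row in df.iterrows():
        if row["start_s"] > row["end_s"]:
            raise SchemaError(f"{path}: event with start after end at data "
                              f"row {i + 2}")
        events.append(Event(float(row["start_s"]), float(row["end_s"]),
                            str(row["label"])))
    for i, (a, b) in enumerate(zip(events, events[1:])):
        if b.start_s < a.end_s:
            raise SchemaError(f"{path}: overlapping events at data row "
                              f"{i + 3}")
    rid = str(df["recording_id"].iloc[0]) if len(df) else ""
    try:
        return EventSequence(events=events, recording_id=rid)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_events(seq: EventSequence, path) -> None:
    pd.DataFrame({
        "recording_id": [seq.recording_id] * len(seq.events),
        "start_s": [e.start_s for e in seq.events],
        "end_s": [e.end_s for e in seq.events],
        "label": [e.label for e in seq.events],
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)
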