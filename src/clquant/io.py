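"""File formats.

All artifacts are small human-diffable text files:

* trace tables — CSV, column 1 ``time_s``, remaining columns one per cell id;
  one file per channel (chloride dye; Fura 340; Fura 380);
* protocols — YAML, ordered steps ``{label, start_s, end_s, cl_mM | stimulus}``;
* behavioral sessions — CSV with columns
  ``mouse_id, genotype, concentration_uM, intake1_ul, intake2_ul, session_type``;
* ground truth / reports — JSON sidecars.

Floats are written with 9 significant digits so re-runs diff cleanly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import SESSION_COLUMNS
from .errors import DataError, ProtocolError

__all__ = [
    "ProtocolStep",
    "read_trace_csv",
    "write_trace_csv",
    "read_protocol",
    "write_protocol",
    "read_sessions_csv",
    "write_sessions_csv",
    "read_json",
    "write_json",
]

FLOAT_FORMAT = "%.9g"


@dataclass(frozen=True)
class ProtocolStep:
    """One ordered step of an imaging protocol.

    Exactly one of ``cl_mM`` (a calibration solution) or ``stimulus`` (an
    applied agonist/label) is set; a plain holding period has neither.
    """

    label: str
    start_s: float
    end_s: float
    cl_mM: float | None = None
    stimulus: str | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ProtocolError(f"step {self.label!r}: end_s must exceed start_s")
        if self.cl_mM is not None and self.stimulus is not None:
            raise ProtocolError(
                f"step {self.label!r}: cl_mM and stimulus are mutually exclusive"
            )


def write_trace_csv(traces: pd.DataFrame, path: str | Path) -> None:
    if "time_s" not in traces.columns:
        raise DataError("trace table must have a time_s column")
    traces.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    traces = pd.read_csv(path)
    if "time_s" not in traces.columns:
        raise DataError(f"{path}: missing time_s column")
    time_s = traces["time_s"].to_numpy()
    bad = np.nonzero(np.diff(time_s) <= 0)[0]
    if bad.size:
        # header is line 1; the offending row is the second of the bad pair
        raise DataError(
            f"{path}: time_s not strictly increasing at data line {bad[0] + 3}"
        )
    return traces


def write_protocol(steps: list[ProtocolStep], path: str | Path) -> None:
    payload = [
        {k: v for k, v in asdict(step).items() if v is not None} for step in steps
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_protocol(path: str | Path) -> list[ProtocolStep]:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise ProtocolError(f"{path}: protocol must be a non-empty list of steps")
    steps = []
    allowed = {"label", "start_s", "end_s", "cl_mM", "stimulus"}
    for i, entry in enumerate(raw):
        unknown = set(entry) - allowed
        if unknown:
            raise ProtocolError(f"{path}: step {i + 1} has unknown keys {sorted(unknown)}")
        try:
            steps.append(ProtocolStep(**entry))
        except TypeError as exc:
            raise ProtocolError(f"{path}: step {i + 1}: {exc}") from exc
    return steps


def write_sessions_csv(sessions: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SESSION_COLUMNS if c not in sessions.columns]
    if missing:
        raise DataError(f"session table is missing columns {missing}")
    sessions[SESSION_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_sessions_csv(path: str | Path) -> pd.DataFrame:
    sessions = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in sessions.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if (sessions[["intake1_ul", "intake2_ul"]] < 0).any().any():
        raise DataError(f"{path}: negative intakes")
    return sessions


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
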