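"""File formats: trace CSV, dose-response CSV, parameter JSON, config.

Trace CSV layout::

    # thapsigargin_time_s=<float>      (optional comment line)
    time_s,ca_cyt_nM
    0,31.2
    ...

Dose-response CSV layout: ``lactate_mM,ca_ss_nM,sem_nM`` (sem optional).
All files are UTF-8 with decimal points; round trips preserve values to
1e-12 relative.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from spermca.model_core import CalciumTrace, CellGeometry, PhysicalParams, ReducedParams
from spermca.steady_state import LactateResponse, SteadyStateParams

__all__ = [
    "TraceIOError",
    "HeaderError",
    "NonMonotonicTimeError",
    "MissingValueError",
    "load_trace",
    "write_trace",
    "load_dose_response",
    "write_dose_response",
    "load_reduced_params",
    "write_reduced_params",
    "load_steady_state_params",
    "write_steady_state_params",
    "load_config",
]

PathLike = Union[str, Path]

TRACE_COLUMNS = ["time_s", "ca_cyt_nM"]
DOSE_COLUMNS = ["lactate_mM", "ca_ss_nM"]
_EVENT_KEY = "thapsigargin_time_s"


class TraceIOError(ValueError):
    """Base class for malformed trace files."""


class HeaderError(TraceIOError):
    """The CSV header does not declare the expected columns."""


class NonMonotonicTimeError(TraceIOError):
    """Sample times are not strictly increasing."""


class MissingValueError(TraceIOError):
    """The file contains NaN or empty cells."""


def _read_csv_with_comments(path: PathLike):
    text = Path(path).read_text(encoding="utf-8")
    comments = [line for line in text.splitlines() if line.startswith("#")]
    body = "\n".join(line for line in text.splitlines() if not line.startswith("#"))
    frame = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    return frame, comments


def load_trace(path: PathLike) -> CalciumTrace:
    """Read a trace CSV; see the module docstring for the layout.

    Raises
    ------
    HeaderError, MissingValueError, NonMonotonicTimeError
    """
    frame, comments = _read_csv_with_comments(path)
    if list(frame.columns) != TRACE_COLUMNS:
        raise HeaderError(
            f"expected header {','.join(TRACE_COLUMNS)!r}, "
            f"got {','.join(map(str, frame.columns))!r}"
        )
    if frame.isna().any().any():
        raise MissingValueError(f"{path}: NaN or empty cells in trace data")
    event = None
    for line in comments:
        stripped = line.lstrip("#").strip()
        if stripped.startswith(_EVENT_KEY + "="):
            event = float(stripped.split("=", 1)[1])
    t = frame["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise NonMonotonicTimeError(f"{path}: times must be strictly increasing")
    return CalciumTrace(t, frame["ca_cyt_nM"].to_numpy(dtype=float),
                        thapsigargin_time=event)


def write_trace(trace: CalciumTrace, path: PathLike) -> None:
    """Write a trace CSV (17 significant digits, lossless round trip)."""
    lines = []
    if trace.thapsigargin_time is not None:
        lines.append(f"# {_EVENT_KEY}={trace.thapsigargin_time!r}")
    lines.append(",".join(TRACE_COLUMNS))
    for t, ca in zip(trace.t, trace.ca_cyt):
        lines.append(f"{t:.17g},{ca:.17g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_dose_response(path: PathLike) -> LactateResponse:
    """Read a dose-response CSV (``lactate_mM,ca_ss_nM[,sem_nM]``)."""
    frame, _ = _read_csv_with_comments(path)
    if list(frame.columns[:2]) != DOSE_COLUMNS:
        raise HeaderError(
            f"expected header to start with {','.join(DOSE_COLUMNS)!r}, "
            f"got {','.join(map(str, frame.columns))!r}"
        )
    sem = frame["sem_nM"].to_numpy(dtype=float) if "sem_nM" in frame.columns else None
    return LactateResponse(
        frame["lactate_mM"].to_numpy(dtype=float),
        frame["ca_ss_nM"].to_numpy(dtype=float),
        sem=sem,
    )


def write_dose_response(data: LactateResponse, path: PathLike) -> None:
    lines = ["lactate_mM,ca_ss_nM" + (",sem_nM" if data.sem is not None else "")]
    for i in range(len(data)):
        row = f"{data.l[i]:.17g},{data.ca_ss[i]:.17g}"
        if data.sem is not None:
            row += f",{data.sem[i]:.17g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_reduced_params(path: PathLike) -> ReducedParams:
    with open(path, encoding="utf-8") as fh:
        return ReducedParams.from_dict(json.load(fh))


def write_reduced_params(params: ReducedParams, path: PathLike) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n",
                          encoding="utf-8")


def load_steady_state_params(path: PathLike) -> SteadyStateParams:
    with open(path, encoding="utf-8") as fh:
        return SteadyStateParams.from_dict(json.load(fh))


def write_steady_state_params(params: SteadyStateParams, path: PathLike) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n",
                          encoding="utf-8")


def load_config(path: PathLike) -> dict:
    """Read a JSON or YAML configuration mapping (YAML is a superset)."""
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return config
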