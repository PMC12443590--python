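"""Reading and writing hemodynamic traces and configuration files.

Traces travel as plain CSV with the fixed header
``time_s,sbp_mmhg,dbp_mmhg,hr_bpm,angle_deg,amplitude_ma``; missing values
are forbidden.  Protocols, patients and controller configurations use YAML
via the ``to_yaml``/``from_yaml`` methods on their classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .patient import BPTimeSeries

__all__ = ["TRACE_COLUMNS", "TraceFormatError", "read_trace", "write_trace"]

TRACE_COLUMNS = ["time_s", "sbp_mmhg", "dbp_mmhg", "hr_bpm", "angle_deg", "amplitude_ma"]

#: fixed float formatting so identical runs produce byte-identical files
_FLOAT_FORMAT = "%.6f"


class TraceFormatError(ValueError):
    """Malformed trace CSV."""


def write_trace(series: BPTimeSeries, path) -> None:
    """Write a trace CSV with the documented header and fixed formatting."""
    df = pd.DataFrame(
        {
            "time_s": series.time,
            "sbp_mmhg": series.sbp,
            "dbp_mmhg": series.dbp,
            "hr_bpm": series.hr,
            "angle_deg": series.angle,
            "amplitude_ma": series.amplitude,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def read_trace(path) -> BPTimeSeries:
    """Read a trace CSV, validating header, monotone time and missing values."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty trace file") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise TraceFormatError(f"{path}: trace has no rows")
    for col in TRACE_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise TraceFormatError(f"{path}: missing value in {col} at line {bad[0] + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        steps = np.diff(t)
        if np.any(steps <= 0):
            line = int(np.argmax(steps <= 0)) + 3
            raise TraceFormatError(f"{path}: non-monotone time at line {line}")
        fs = 1.0 / steps[0]
    else:
        fs = 1.0
    return BPTimeSeries(
        time=t,
        sbp=df["sbp_mmhg"].to_numpy(dtype=float),
        dbp=df["dbp_mmhg"].to_numpy(dtype=float),
        hr=df["hr_bpm"].to_numpy(dtype=float),
        angle=df["angle_deg"].to_numpy(dtype=float),
        amplitude=df["amplitude_ma"].to_numpy(dtype=float),
        fs=fs,
    )
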