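"""End-to-end experiment driver: simulate, control, measure, report.

``run_experiment`` couples a patient twin, a tilt protocol and a stimulation
mode (none / continuous / closed-loop / IMU), computes the standard metrics
and returns a JSON-serializable report that embeds the resolved
configuration so every number is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .controller import (
    ControllerConfig,
    PositionMap,
    run_closed_loop,
    run_continuous,
    run_imu_loop,
)
from .metrics import bp_change_tilt, challenge_errors, time_to_tilt_end
from .patient import BPTimeSeries, PatientParams, simulate
from .protocols import TiltProtocol

__all__ = ["RunConfig", "run_experiment"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    patient: PatientParams
    protocol: TiltProtocol
    mode: str = "none"  # none | continuous | closed-loop | imu
    controller: Optional[ControllerConfig] = None
    position_map: Optional[PositionMap] = None
    amplitude: float = 0.0      # mA, continuous mode
    duration: Optional[float] = None  # s; defaults to the protocol duration
    seed: int = 0
    challenge_start: Optional[float] = None  # s; default: first tilted segment
    challenge_end: Optional[float] = None    # s; default: last tilted segment end

    def __post_init__(self) -> None:
        if self.mode not in ("none", "continuous", "closed-loop", "imu"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "closed-loop" and self.controller is None:
            raise ValueError("closed-loop mode needs a controller config")
        if self.mode == "imu" and self.position_map is None:
            raise ValueError("imu mode needs a position map")


def _challenge_window(protocol: TiltProtocol) -> tuple[float, float]:
    starts = protocol.segment_starts()
    tilted = [
        (s, s + seg.duration)
        for s, seg in zip(starts, protocol.segments)
        if seg.angle > 0
    ]
    if not tilted:
        return 0.0, protocol.duration
    return float(tilted[0][0]), float(tilted[-1][1])


def run_experiment(config: RunConfig) -> dict:
    """Execute one run and return the metrics report (a plain dict)."""
    duration = config.duration if config.duration is not None else config.protocol.duration
    if config.mode == "none":
        trace = simulate(config.patient, config.protocol, 0.0, duration, seed=config.seed)
    elif config.mode == "continuous":
        trace = run_continuous(
            config.patient, config.protocol, config.amplitude, duration, seed=config.seed
        )
    elif config.mode == "closed-loop":
        trace = run_closed_loop(
            config.patient, config.protocol, config.controller, duration, seed=config.seed
        )
    else:
        trace = run_imu_loop(
            config.patient, config.protocol, config.position_map, duration,
            seed=config.seed, config=config.controller,
        )

    c_start = config.challenge_start
    c_end = config.challenge_end
    if c_start is None or c_end is None:
        d_start, d_end = _challenge_window(config.protocol)
        c_start = d_start if c_start is None else c_start
        c_end = d_end if c_end is None else c_end

    report: dict = {
        "software": {"name": "hemoloop", "version": __version__},
        "config": {
            "mode": config.mode,
            "seed": config.seed,
            "duration_s": duration,
            "amplitude_ma": config.amplitude,
            "patient": config.patient.to_dict(),
            "protocol": config.protocol.to_dict(),
            "controller": config.controller.to_dict() if config.controller else None,
        },
        "metrics": {},
    }
    m = report["metrics"]
    if c_end > c_start and c_start >= 0:
        try:
            for ch in ("sbp", "dbp", "hr"):
                m[f"bp_change_tilt_{ch}"] = bp_change_tilt(trace, c_start, c_end, channel=ch)
        except ValueError:
            pass  # protocol without a usable baseline window
        target = config.controller.target if config.controller else config.patient.sbp_baseline
        margin = min(60.0, c_start, max(0.0, duration - c_end))
        try:
            ce = challenge_errors(trace, target, c_start, c_end, margin=margin)
            m["target_error_mean"] = ce.target_error_mean
            m["target_error_mean_abs"] = ce.target_error_mean_abs
            m["error_variability"] = ce.error_variability
        except ValueError:
            pass
        elapsed, event = time_to_tilt_end(trace, c_start)
        m["tilt_time_s"] = elapsed
        m["tilt_terminated"] = bool(event)
    m["sbp_mean"] = float(np.mean(trace.sbp))
    m["amplitude_max"] = float(np.max(trace.amplitude))
    report["_trace"] = trace  # stripped before JSON serialization
    return report


def report_to_json(report: dict, path) -> None:
    """Write a report (without the in-memory trace) as deterministic JSON."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
        fh.write("\n")
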