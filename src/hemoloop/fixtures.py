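"""Seeded synthetic fixture bundles standing in for clinical recordings.

Each bundle is written as plain-text files (trace CSV, protocol YAML,
expected-metric JSON computed by the package itself) and is bit-identical
for identical seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import fit_calibration
from .controller import ControllerConfig, run_closed_loop
from .io import write_trace
from .metrics import bp_change_tilt, challenge_errors
from .patient import PatientParams, simulate
from .physio import synth_neurogram
from .protocols import (
    TiltProtocol,
    make_dynamic_tilt,
    make_formal_tilt,
    make_staircase,
    with_padding,
)

__all__ = ["FIXTURE_KINDS", "make_fixture"]

FIXTURE_KINDS = ("formal_tilt", "dynamic_tilt", "staircase", "neurogram")


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_fixture(kind: str, seed: int, outdir) -> list[Path]:
    """Generate one fixture bundle; returns the list of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = PatientParams()
    written: list[Path] = []

    if kind == "formal_tilt":
        protocol = make_formal_tilt(70.0, 300.0, 600.0)
        trace = simulate(params, protocol, 0.0, protocol.duration, seed=seed)
        trace_path = outdir / "trace.csv"
        write_trace(trace, trace_path)
        protocol.to_yaml(outdir / "protocol.yaml")
        delta = bp_change_tilt(trace, 300.0, 900.0)
        _write_json(
            {"bp_change_tilt_sbp": delta, "tilt_start_s": 300.0, "tilt_end_s": 900.0},
            outdir / "expected.json",
        )
        written = [trace_path, outdir / "protocol.yaml", outdir / "expected.json"]

    elif kind == "dynamic_tilt":
        dynamic = make_dynamic_tilt(seed)
        protocol = with_padding(dynamic, 60.0, 60.0)
        config = ControllerConfig(
            kp=1.0 / params.pressor_gain,
            ki=1.0 / (params.pressor_gain * 30.0),
            target=params.sbp_baseline,
            amp_max=params.amp_saturation,
        )
        trace = run_closed_loop(params, protocol, config, protocol.duration, seed=seed)
        c_start, c_end = 60.0, 60.0 + dynamic.duration
        ce = challenge_errors(trace, config.target, c_start, c_end, margin=60.0)
        trace_path = outdir / "trace.csv"
        write_trace(trace, trace_path)
        protocol.to_yaml(outdir / "protocol.yaml")
        _write_json(
            {
                "target_error_mean": ce.target_error_mean,
                "target_error_mean_abs": ce.target_error_mean_abs,
                "error_variability": ce.error_variability,
                "n_angle_changes": len(dynamic.segments),
            },
            outdir / "expected.json",
        )
        written = [trace_path, outdir / "protocol.yaml", outdir / "expected.json"]

    elif kind == "staircase":
        schedule = make_staircase(1.0, 60.0, params.amp_saturation + 2.0)
        duration = schedule.breakpoints[-1][0] + 60.0
        protocol = TiltProtocol.from_dict(
            {"transition_rate_deg_per_s": 2.0,
             "segments": [{"angle_deg": 0.0, "duration_s": duration}]}
        )
        trace = simulate(params, protocol, schedule, duration, seed=seed)
        cal = fit_calibration(trace, schedule)
        trace_path = outdir / "trace.csv"
        write_trace(trace, trace_path)
        schedule.to_yaml(outdir / "schedule.yaml")
        cal.to_json(outdir / "calibration.json")
        written = [trace_path, outdir / "schedule.yaml", outdir / "calibration.json"]

    elif kind == "neurogram":
        ng, truth = synth_neurogram(seed, duration=8.0, n_spikes=10)
        df = pd.DataFrame({"sample_v": ng.samples})
        csv_path = outdir / "neurogram.csv"
        df.to_csv(csv_path, index=False, float_format="%.6f", lineterminator="\n")
        _write_json(
            {
                "fs_hz": ng.fs,
                "baseline_window_s": list(ng.baseline_window),
                "true_spike_times_s": [round(float(t), 6) for t in truth],
            },
            outdir / "expected.json",
        )
        written = [csv_path, outdir / "expected.json"]

    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")

    return written
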