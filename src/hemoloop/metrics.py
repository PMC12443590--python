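"""Windowed blood-pressure change definitions and controller performance metrics.

All windows are half-open ``[a, b)`` over the sample timestamps of the 1 Hz
stream; "before the start" therefore excludes the start sample itself.  The
"20-s window at 3 min" is centered on the 3-minute mark, i.e. [t+170, t+190).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .patient import BPTimeSeries

__all__ = [
    "ChallengeMetrics",
    "CoverageError",
    "bp_change_tilt",
    "bp_change_seated",
    "bp_change_intraop",
    "postprandial_delta",
    "challenge_errors",
    "smooth_display",
    "time_to_tilt_end",
]


class CoverageError(ValueError):
    """The series does not cover a required analysis window."""


@dataclass(frozen=True)
class ChallengeMetrics:
    """Target error statistics over a dynamic-challenge window.

    ``target_error_mean`` is the signed mean of SBP - target;
    ``target_error_mean_abs`` is the mean absolute error;
    ``error_variability`` is the sample s.d. of the error.
    """

    target_error_mean: float
    target_error_mean_abs: float
    error_variability: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.error_variability < 0:
            raise ValueError("error_variability must be >= 0")
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede end")


def _window_mean(series: BPTimeSeries, channel: str, start: float, end: float, name: str) -> float:
    mask = series.window_mask(start, end)
    if not np.any(mask):
        raise CoverageError(f"series does not cover the {name} window [{start}, {end})")
    return float(np.mean(series.channel(channel)[mask]))


def bp_change_tilt(
    series: BPTimeSeries,
    tilt_start: float,
    tilt_end: float,
    channel: str = "sbp",
) -> float:
    """Pressure change over an orthostatic challenge (negative = drop).

    Difference between the mean of a 60-s window before the tilt start and a
    20-s window centered at 3 min of the challenge; for tilts ended early
    (before 3 min), a 20-s window before the tilt end is used instead.
    """
    if tilt_end <= tilt_start:
        raise ValueError("tilt_end must be after tilt_start")
    baseline = _window_mean(series, channel, tilt_start - 60.0, tilt_start, "baseline")
    if tilt_end - tilt_start >= 180.0:
        comp = _window_mean(
            series, channel, tilt_start + 170.0, tilt_start + 190.0, "3-min"
        )
    else:
        comp = _window_mean(series, channel, tilt_end - 20.0, tilt_end, "tilt-end")
    return comp - baseline


def bp_change_seated(
    series: BPTimeSeries,
    stim_on: float,
    stim_off: float,
    channel: str = "sbp",
) -> float:
    """Pressure change for seated stimulation: 20-s window at 3 min after
    stimulation onset minus the 20-s window before onset."""
    if stim_off - stim_on < 180.0:
        raise ValueError("seated stimulation must last at least 3 min")
    pre = _window_mean(series, channel, stim_on - 20.0, stim_on, "pre-stimulation")
    post = _window_mean(series, channel, stim_on + 170.0, stim_on + 190.0, "3-min")
    return post - pre


def bp_change_intraop(
    series: BPTimeSeries,
    stim_start: float,
    stim_end: float,
    channel: str = "sbp",
) -> float:
    """Intraoperative pressure change: 30-s window ending at stimulation end
    minus the 30-s window before stimulation start.

    For stimulations shorter than 30 s the two windows overlap; they are
    still computed exactly as specified.
    """
    if stim_end <= stim_start:
        raise ValueError("stim_end must be after stim_start")
    pre = _window_mean(series, channel, stim_start - 30.0, stim_start, "pre-stimulation")
    post = _window_mean(series, channel, stim_end - 30.0, stim_end, "end-of-stimulation")
    return post - pre


def postprandial_delta(
    baseline_cuff: Sequence[float],
    post_cuff: Sequence[tuple[float, float]],
    window_min: float = 30.0,
    window_max: float = 60.0,
) -> float:
    """Postprandial pressure change from arm-cuff measurements.

    Mean of the cuff values taken between 30 and 60 min (inclusive) after the
    meal minus the mean of all pre-meal baseline values.
    """
    base = np.asarray(baseline_cuff, dtype=float)
    if base.size == 0:
        raise ValueError("need at least one baseline measurement")
    post = [v for t, v in post_cuff if window_min <= t <= window_max]
    if not post:
        raise CoverageError(
            f"no cuff measurement in the [{window_min}, {window_max}] min window"
        )
    return float(np.mean(post) - np.mean(base))


def challenge_errors(
    series: BPTimeSeries,
    target: float,
    challenge_start: float,
    challenge_end: float,
    margin: float = 60.0,
) -> ChallengeMetrics:
    """Target error and error variability over a dynamic challenge.

    Computed from ``margin`` seconds before the challenge to ``margin``
    seconds after its end (default 1 min each side).  Error variability is
    the sample (ddof=1) standard deviation of SBP - target.
    """
    start, end = challenge_start - margin, challenge_end + margin
    mask = series.window_mask(start, end)
    n = int(np.sum(mask))
    if n < 2:
        raise CoverageError(f"series does not cover the challenge window [{start}, {end})")
    e = series.sbp[mask] - target
    return ChallengeMetrics(
        target_error_mean=float(np.mean(e)),
        target_error_mean_abs=float(np.mean(np.abs(e))),
        error_variability=float(np.std(e, ddof=1)),
        window=(start, end),
    )


def smooth_display(series: BPTimeSeries, window: float = 10.0) -> BPTimeSeries:
    """Centered moving-average smoothing of the pressure/HR channels for
    illustration; the window shrinks at the edges.  Angle and amplitude
    channels are left untouched."""
    n_win = int(round(window * series.fs))
    if n_win < 1:
        raise ValueError("window must cover at least one sample")

    def smooth(x: np.ndarray) -> np.ndarray:
        half_lo = (n_win - 1) // 2
        half_hi = n_win // 2
        out = np.empty_like(x, dtype=float)
        for i in range(len(x)):
            lo = max(0, i - half_lo)
            hi = min(len(x), i + half_hi + 1)
            out[i] = np.mean(x[lo:hi])
        return out

    return BPTimeSeries(
        time=series.time.copy(),
        sbp=smooth(series.sbp),
        dbp=smooth(series.dbp),
        hr=smooth(series.hr),
        angle=series.angle.copy(),
        amplitude=series.amplitude.copy(),
        fs=series.fs,
        termination_time=series.termination_time,
    )


def time_to_tilt_end(
    trace: BPTimeSeries,
    tilt_start: float,
    criterion: Optional[tuple[float, float]] = None,
) -> tuple[float, bool]:
    """Elapsed time from tilt start to intolerance, or to the end of the
    recording (censored).

    Returns ``(elapsed_s, event)`` where ``event`` is True for a genuine
    termination.  With ``criterion=(threshold_mmhg, hold_s)`` the breach is
    recomputed from the trace (SBP below threshold for ``hold_s`` continuous
    seconds while tilted); with ``criterion=None`` the simulator's
    termination flag is used, and a missing flag means censored.
    """
    if tilt_start < trace.time[0] or tilt_start > trace.time[-1]:
        raise ValueError("tilt_start outside the recorded trace")
    end = trace.time[-1] + 1.0 / trace.fs
    if criterion is None:
        t_term = trace.termination_time
        if t_term is not None and t_term >= tilt_start:
            return float(t_term - tilt_start), True
        return float(end - tilt_start), False
    threshold, hold = criterion
    dt = 1.0 / trace.fs
    below_since = None
    for t, sbp, ang in zip(trace.time, trace.sbp, trace.angle):
        if t < tilt_start:
            continue
        if ang > 0 and sbp < threshold:
            if below_since is None:
                below_since = t
            if t - below_since + dt >= hold:
                return float(t - tilt_start), True
        else:
            below_since = None
    return float(end - tilt_start), False
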