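"""Calibration of the amplitude -> systolic pressure relation.

A seated staircase session (amplitude raised 1 mA every minute by default)
yields a mean systolic pressure per stimulation level.  The operating range
is the span of levels over which the pressure keeps rising; an ordinary
least-squares regression of mean SBP on amplitude over that range gives the
slope that seeds the controller gains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .controller import ControllerConfig
from .patient import BPTimeSeries
from .protocols import StimSchedule

__all__ = ["Calibration", "NoOperatingRangeError", "fit_calibration", "initial_gains"]

#: portion of each staircase level excluded as settling transient, s
SETTLE_EXCLUDE = 30.0


class NoOperatingRangeError(RuntimeError):
    """Raised when no staircase level shows the required pressure rise."""


@dataclass(frozen=True)
class Calibration:
    """Linear operating range and amplitude->SBP regression."""

    amp_min: float    # mA, first level with a pressor rise
    amp_max: float    # mA, last level still rising
    slope: float      # mm Hg per mA
    intercept: float  # mm Hg
    r_squared: float
    per_level_means: tuple[tuple[float, float], ...]  # (amplitude mA, mean SBP)

    def __post_init__(self) -> None:
        if not self.amp_min < self.amp_max:
            raise ValueError("amp_min must be < amp_max")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")
        amps = [a for a, _ in self.per_level_means]
        if any(a2 <= a1 for a1, a2 in zip(amps, amps[1:])):
            raise ValueError("per-level amplitudes must be strictly increasing")

    def predict(self, amplitude: float) -> float:
        return self.intercept + self.slope * amplitude

    def to_dict(self) -> dict:
        return {
            "amp_min": self.amp_min,
            "amp_max": self.amp_max,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "per_level_means": [[a, m] for a, m in self.per_level_means],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            d["amp_min"], d["amp_max"], d["slope"], d["intercept"], d["r_squared"],
            tuple((a, m) for a, m in d["per_level_means"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Calibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_calibration(
    series: BPTimeSeries,
    schedule: StimSchedule,
    rise_threshold: float = 2.0,
) -> Calibration:
    """Find the linear operating range and fit the amplitude->SBP regression.

    Per-level mean SBP is computed over the settled part of each level (the
    level minus the first ``SETTLE_EXCLUDE`` seconds, or the last half of a
    short level).  The minimum of the range is the first level whose mean
    exceeds the 0 mA mean by at least ``rise_threshold``; the maximum is the
    last level that still exceeds its predecessor by ``rise_threshold``.
    """
    if len(schedule.breakpoints) < 3:
        raise ValueError("need at least 3 staircase levels")
    times = [t for t, _ in schedule.breakpoints]
    amps = [a for _, a in schedule.breakpoints]
    t_end_series = float(series.time[-1]) + 1.0 / series.fs
    edges = times + [t_end_series]

    level_amps: list[float] = []
    level_means: list[float] = []
    for i, amp in enumerate(amps):
        start, end = edges[i], min(edges[i + 1], t_end_series)
        if end <= start:
            continue
        settle = start + min(SETTLE_EXCLUDE, (end - start) / 2.0)
        mask = series.window_mask(settle, end)
        if not np.any(mask):
            raise ValueError(f"series does not cover staircase level at {amp} mA")
        level_amps.append(float(amp))
        level_means.append(float(np.mean(series.sbp[mask])))

    if len(level_means) < 3:
        raise ValueError("need at least 3 covered staircase levels")

    base_mean = level_means[0]
    rising_min = [
        i for i in range(1, len(level_means))
        if level_means[i] - base_mean >= rise_threshold
    ]
    rising_step = [
        i for i in range(1, len(level_means))
        if level_means[i] - level_means[i - 1] >= rise_threshold
    ]
    if not rising_min or not rising_step:
        raise NoOperatingRangeError(
            f"no staircase level rose by >= {rise_threshold} mm Hg"
        )
    i_min, i_max = rising_min[0], rising_step[-1]
    if i_max < i_min:
        raise NoOperatingRangeError("operating range is empty")
    amp_min, amp_max = level_amps[i_min], level_amps[i_max]

    in_range = [i for i in range(len(level_amps)) if amp_min <= level_amps[i] <= amp_max]
    if len(in_range) < 2:
        raise NoOperatingRangeError("fewer than 2 levels in the operating range")
    x = np.array([level_amps[i] for i in in_range])
    y = np.array([level_means[i] for i in in_range])
    fit = _stats.linregress(x, y)
    r2 = float(fit.rvalue**2) if len(x) > 2 else 1.0
    return Calibration(
        amp_min=amp_min,
        amp_max=amp_max,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(r2, 1.0),
        per_level_means=tuple(zip(level_amps, level_means)),
    )


def initial_gains(
    cal: Calibration,
    target: float,
    ti: float = 30.0,
    td: float = 0.0,
    **overrides,
) -> ControllerConfig:
    """Seed a controller configuration from a calibration.

    The proportional gain inverts the calibration slope (the regression maps
    mA to mm Hg; the controller maps a pressure error back to mA), and the
    integral/derivative gains follow PI(D) ratios in the Ziegler-Nichols
    spirit: Ki = Kp/Ti, Kd = Kp*Td.  The amplitude range is [0, cal.amp_max].
    """
    if not 60 <= target <= 200:
        raise ValueError("target must be a plausible SBP (60-200 mm Hg)")
    if cal.slope <= 0:
        raise ValueError("non-positive calibration slope: controller polarity undefined")
    kp = 1.0 / cal.slope
    ki = kp / ti if ti > 0 else 0.0
    kd = kp * td
    kwargs = dict(
        kp=kp, ki=ki, kd=kd, target=float(target), amp_min=0.0, amp_max=cal.amp_max
    )
    kwargs.update(overrides)
    return ControllerConfig(**kwargs)
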