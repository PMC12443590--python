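"""Tilt-table and stimulation protocols.

A tilt protocol is an ordered list of (angle, hold-duration) segments; the
table moves between segments at a finite ``transition_rate`` so the implied
angle trace is continuous and piecewise linear.  Stimulation schedules are
step functions of amplitude over time at fixed frequency and pulse width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TiltSegment",
    "TiltProtocol",
    "StimSchedule",
    "make_formal_tilt",
    "make_dynamic_tilt",
    "make_staircase",
    "with_padding",
]

#: default table speed, deg/s; reaches 70 deg in 35 s (< 45 s verticalization)
DEFAULT_TRANSITION_RATE = 2.0


@dataclass(frozen=True)
class TiltSegment:
    """One held tilt position: ``angle`` deg from horizontal, ``duration`` s."""

    angle: float
    duration: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle <= 90.0:
            raise ValueError(f"tilt angle must be in [0, 90] deg, got {self.angle}")
        if not self.duration > 0:
            raise ValueError(f"segment duration must be > 0 s, got {self.duration}")


@dataclass(frozen=True)
class TiltProtocol:
    """Ordered tilt segments plus the table transition rate (deg/s).

    The angle trace starts at the first segment's angle.  Each subsequent
    segment begins with a linear transition from the previous angle at
    ``transition_rate``; transition time counts against the segment's hold.
    """

    segments: tuple[TiltSegment, ...]
    transition_rate: float = DEFAULT_TRANSITION_RATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if len(self.segments) == 0:
            raise ValueError("protocol needs at least one segment")
        if not self.transition_rate > 0:
            raise ValueError("transition_rate must be > 0 deg/s")
        for seg in self.segments:
            ramp = abs(seg.angle) / self.transition_rate
            # a segment must be long enough to at least reach its angle
            if seg.duration <= 0:
                raise ValueError("non-positive segment duration")

    @property
    def duration(self) -> float:
        """Total protocol duration in seconds."""
        return float(sum(s.duration for s in self.segments))

    def segment_starts(self) -> np.ndarray:
        """Start time of each segment."""
        durs = np.array([s.duration for s in self.segments])
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    def angle_at(self, t: float) -> float:
        """Tilt angle (deg) at time ``t``; clamped to the last angle after the end."""
        starts = self.segment_starts()
        if t <= 0:
            return self.segments[0].angle
        idx = int(np.searchsorted(starts, t, side="right") - 1)
        idx = min(idx, len(self.segments) - 1)
        target = self.segments[idx].angle
        prev = self.segments[idx - 1].angle if idx > 0 else self.segments[0].angle
        elapsed = t - starts[idx]
        delta = target - prev
        if delta == 0:
            return target
        step = np.sign(delta) * min(abs(delta), self.transition_rate * elapsed)
        return float(prev + step)

    def angle_trace(self, times: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`angle_at` over an array of times."""
        return np.array([self.angle_at(float(t)) for t in np.asarray(times)])

    # -- plain-text serialization -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "transition_rate_deg_per_s": self.transition_rate,
            "segments": [
                {"angle_deg": s.angle, "duration_s": s.duration} for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TiltProtocol":
        segs = [TiltSegment(s["angle_deg"], s["duration_s"]) for s in d["segments"]]
        return cls(tuple(segs), d.get("transition_rate_deg_per_s", DEFAULT_TRANSITION_RATE))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TiltProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class StimSchedule:
    """Piecewise-constant amplitude schedule at fixed frequency / pulse width.

    ``breakpoints`` is an ordered list of (time s, amplitude mA); the
    amplitude holds from each breakpoint until the next one.
    """

    breakpoints: tuple[tuple[float, float], ...]
    frequency: float = 120.0       # Hz
    pulse_width: float = 300.0     # microseconds

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "breakpoints", tuple((float(t), float(a)) for t, a in self.breakpoints)
        )
        times = [t for t, _ in self.breakpoints]
        amps = [a for _, a in self.breakpoints]
        if len(times) == 0:
            raise ValueError("schedule needs at least one breakpoint")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be >= 0 mA")
        if not (self.frequency > 0 and self.pulse_width > 0):
            raise ValueError("frequency and pulse width must be positive")

    def amplitude_at(self, t: float) -> float:
        """Amplitude (mA) in effect at time ``t`` (0 before the first breakpoint)."""
        amp = 0.0
        for bt, ba in self.breakpoints:
            if t >= bt:
                amp = ba
            else:
                break
        return amp

    def to_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency,
            "pulse_width_us": self.pulse_width,
            "breakpoints": [{"time_s": t, "amplitude_ma": a} for t, a in self.breakpoints],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimSchedule":
        bps = tuple((b["time_s"], b["amplitude_ma"]) for b in d["breakpoints"])
        return cls(bps, d.get("frequency_hz", 120.0), d.get("pulse_width_us", 300.0))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StimSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_formal_tilt(
    angle: float,
    baseline_duration: float,
    tilt_duration: float,
    transition_rate: float = DEFAULT_TRANSITION_RATE,
) -> TiltProtocol:
    """Standard head-up tilt: supine baseline then a single held tilt.

    The verticalization must complete in under 45 s, so the transition rate
    is raised to ``angle / 45`` deg/s when the requested rate is too slow.
    """
    if not 0 <= angle <= 90:
        raise ValueError(f"tilt angle must be in [0, 90] deg, got {angle}")
    if baseline_duration <= 0 or tilt_duration <= 0:
        raise ValueError("durations must be positive")
    rate = max(transition_rate, angle / 45.0) if angle > 0 else transition_rate
    return TiltProtocol(
        (TiltSegment(0.0, baseline_duration), TiltSegment(angle, tilt_duration)),
        transition_rate=rate,
    )


def make_dynamic_tilt(
    seed: int,
    n_changes: int = 8,
    angle_min: float = 20.0,
    angle_max: float = 80.0,
    hold_min: float = 60.0,
    hold_max: float = 120.0,
    angle_grid: float = 10.0,
    transition_rate: float = DEFAULT_TRANSITION_RATE,
) -> TiltProtocol:
    """Seeded pseudo-random dynamic orthostatic challenge.

    Draws ``n_changes`` tilt positions uniformly from a 10-degree grid within
    [angle_min, angle_max] (matching realistic tilt-table settings) with hold
    durations uniform on [hold_min, hold_max].  Consecutive segments always
    differ in angle, so each segment is a genuine change, unless the angle
    range is degenerate.
    """
    if n_changes < 1:
        raise ValueError("n_changes must be >= 1")
    if angle_min > angle_max or not (0 <= angle_min and angle_max <= 90):
        raise ValueError("need 0 <= angle_min <= angle_max <= 90")
    if hold_min > hold_max or hold_min <= 0:
        raise ValueError("need 0 < hold_min <= hold_max")
    rng = np.random.default_rng(seed)
    n_grid = int(np.floor((angle_max - angle_min) / angle_grid)) + 1
    angles: list[float] = []
    for _ in range(n_changes):
        a = angle_min + angle_grid * rng.integers(0, n_grid)
        if n_grid > 1:
            while angles and a == angles[-1]:
                a = angle_min + angle_grid * rng.integers(0, n_grid)
        angles.append(float(a))
    holds = rng.uniform(hold_min, hold_max, size=n_changes)
    segs = tuple(TiltSegment(a, float(h)) for a, h in zip(angles, holds))
    return TiltProtocol(segs, transition_rate=transition_rate)


def make_staircase(
    step: float = 1.0,
    interval: float = 60.0,
    max_amplitude: float = 10.0,
    frequency: float = 120.0,
    pulse_width: float = 300.0,
) -> StimSchedule:
    """Calibration staircase: amplitude 0, step, 2*step, ... up to max_amplitude.

    Default 1 mA steps every 60 s, the seated titration used to find the
    linear operating range.
    """
    if step <= 0 or interval <= 0:
        raise ValueError("step and interval must be positive")
    if max_amplitude < step:
        raise ValueError("max_amplitude must be >= step")
    n_levels = int(np.floor(max_amplitude / step + 1e-12)) + 1
    bps = tuple((i * interval, i * step) for i in range(n_levels))
    return StimSchedule(bps, frequency=frequency, pulse_width=pulse_width)


def with_padding(protocol: TiltProtocol, pre: float = 60.0, post: float = 60.0) -> TiltProtocol:
    """Surround a protocol with supine (0 deg) rest before and after."""
    segs = list(protocol.segments)
    if pre > 0:
        segs = [TiltSegment(0.0, pre)] + segs
    if post > 0:
        segs = segs + [TiltSegment(0.0, post)]
    return TiltProtocol(tuple(segs), transition_rate=protocol.transition_rate)
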