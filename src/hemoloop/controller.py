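"""Closed-loop PID blood-pressure controller and comparator controllers.

The control chain each period: the 1 Hz systolic stream is smoothed with an
exponentially weighted moving average over a trailing window; the smoothed
value feeds a PID law with a +/-3 mm Hg deadband, an integral forgetting
factor, and a saturation (anti-windup) penalty; the commanded amplitude is
finally rate-limited by a comfort ramp (0.5 mA per 500 ms by default).

Comparator controllers: constant-amplitude ("continuous") stimulation and an
IMU-based position controller that maps accelerometer-derived tilt angle to
fixed amplitudes for supine / seated / standing bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from . import patient as _patient
from .patient import BPTimeSeries, PatientParams
from .protocols import TiltProtocol

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "PositionMap",
    "ewma_smooth",
    "pid_step",
    "ramp_output",
    "run_closed_loop",
    "run_continuous",
    "run_imu_loop",
    "angle_from_accel",
    "ClosedLoopDriver",
]


@dataclass(frozen=True)
class ControllerConfig:
    """PID gains, target and actuation constraints.

    ``deadband_mode`` selects what happens around target +/- deadband:
    ``"hold"`` (default) is a hysteresis — once the smoothed pressure is
    inside the deadband and active control has brought the error below
    ``inner_band``, the command and controller memory are frozen (no
    actuation inside the target range) until the error leaves the deadband
    again; ``"zero"`` literally zeroes the error inside the deadband while
    the rest of the recurrence keeps running.  ``ewma_mode`` selects the
    smoother reading of the forgetting factor: ``"window"``
    (trailing-window weights (1-forget)^lag, normalized) or ``"recursive"``
    (y <- forget*x + (1-forget)*y).
    """

    kp: float                    # mA per mm Hg
    ki: float = 0.0              # mA per (mm Hg * s)
    kd: float = 0.0              # mA * s per mm Hg
    target: float = 120.0        # mm Hg
    deadband: float = 3.0        # mm Hg
    inner_band: float = 0.5      # mm Hg; hysteresis re-hold margin ("hold" mode)
    integral_forget: float = 0.999   # rho, per control step
    windup_penalty: float = 0.9      # gamma, per saturated-and-unchanged step
    ramp_step: float = 0.5       # mA
    ramp_interval: float = 0.5   # s
    ramp_trigger: float = 0.5    # mA; larger commanded changes are ramped
    amp_min: float = 0.0         # mA
    amp_max: float = 12.0        # mA
    ewma_window: float = 3.0     # s
    ewma_forget: float = 0.3
    control_period: float = 1.0  # s
    deadband_mode: str = "hold"
    ewma_mode: str = "window"

    def __post_init__(self) -> None:
        if self.deadband < 0:
            raise ValueError("deadband must be >= 0")
        if self.inner_band < 0:
            raise ValueError("inner_band must be >= 0")
        if not 0 < self.integral_forget <= 1:
            raise ValueError("integral_forget must be in (0, 1]")
        if not 0 < self.windup_penalty <= 1:
            raise ValueError("windup_penalty must be in (0, 1]")
        if not self.amp_min < self.amp_max:
            raise ValueError("amp_min must be < amp_max")
        if not 0 < self.ewma_forget < 1:
            raise ValueError("ewma_forget must be in (0, 1)")
        if self.control_period <= 0:
            raise ValueError("control_period must be > 0")
        if self.ramp_step <= 0 or self.ramp_interval <= 0 or self.ramp_trigger < 0:
            raise ValueError("ramp parameters must be positive")
        if self.deadband_mode not in ("hold", "zero"):
            raise ValueError("deadband_mode must be 'hold' or 'zero'")
        if self.ewma_mode not in ("window", "recursive"):
            raise ValueError("ewma_mode must be 'window' or 'recursive'")

    def to_dict(self) -> dict:
        return {
            "kp": self.kp, "ki": self.ki, "kd": self.kd, "target": self.target,
            "deadband": self.deadband, "integral_forget": self.integral_forget,
            "windup_penalty": self.windup_penalty, "ramp_step": self.ramp_step,
            "ramp_interval": self.ramp_interval, "ramp_trigger": self.ramp_trigger,
            "amp_min": self.amp_min, "amp_max": self.amp_max,
            "ewma_window": self.ewma_window, "ewma_forget": self.ewma_forget,
            "control_period": self.control_period,
            "deadband_mode": self.deadband_mode, "ewma_mode": self.ewma_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ControllerConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ControllerState:
    """Evolving controller memory; treat as immutable, ``pid_step`` returns a copy."""

    integral: float = 0.0          # mm Hg * s
    previous_error: float = 0.0    # mm Hg
    last_command: float = 0.0      # mA, last (clipped) PID command
    emitted: float = 0.0           # mA, last ramp-limited output
    active: bool = False           # False while held inside the deadband


def ewma_smooth(
    samples: Sequence[float],
    window: float = 3.0,
    forget: float = 0.3,
    fs: float = 1.0,
    mode: str = "window",
) -> float:
    """Exponentially weighted moving average of the trailing ``window`` seconds.

    ``mode="window"``: weight (1-forget)^lag per sample inside the window
    (newest lag 0), normalized to sum 1.  ``mode="recursive"``: the classic
    one-pole update y <- forget*x + (1-forget)*y over the full sequence,
    which has the same per-lag decay but an unbounded memory.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("ewma_smooth needs at least one sample")
    if not 0 < forget < 1:
        raise ValueError("forget must be in (0, 1)")
    if mode == "recursive":
        y = x[0]
        for v in x[1:]:
            y = forget * v + (1.0 - forget) * y
        return float(y)
    n = max(1, int(round(window * fs)))
    tail = x[-n:]
    lags = np.arange(len(tail) - 1, -1, -1)   # oldest..newest -> lag high..0
    w = (1.0 - forget) ** lags
    return float(np.dot(w, tail) / np.sum(w))


def pid_step(
    config: ControllerConfig,
    state: ControllerState,
    smoothed_sbp: float,
    dt: float,
) -> tuple[float, ControllerState]:
    """One PID update; returns the clipped command (mA) and the new state.

    Update order: deadband on the error, integral forgetting + accumulation,
    derivative on the (smoothed) error, control law, clip to the amplitude
    range, then the anti-windup penalty when the clipped command equals the
    previous command and sits at a range bound.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not np.isfinite(smoothed_sbp):
        raise ValueError("non-finite smoothed SBP")
    e = config.target - smoothed_sbp
    in_band = abs(e) <= config.deadband
    if config.deadband_mode == "hold":
        inner = min(config.inner_band, config.deadband)
        if in_band and not state.active:
            # held: no actuation while the pressure stays in the target range
            return state.last_command, replace(state, previous_error=0.0)
        if state.active and abs(e) <= inner:
            # active control has reached the target: freeze until the
            # pressure leaves the deadband again
            return state.last_command, replace(state, previous_error=0.0, active=False)
    elif in_band:
        e = 0.0
    integral = config.integral_forget * state.integral + e * dt
    derivative = (e - state.previous_error) / dt
    u = config.kp * e + config.ki * integral + config.kd * derivative
    cmd = min(max(u, config.amp_min), config.amp_max)
    if cmd == state.last_command and cmd in (config.amp_min, config.amp_max):
        integral *= config.windup_penalty
    return cmd, replace(
        state, integral=integral, previous_error=e, last_command=cmd, active=True
    )


def ramp_output(
    config: ControllerConfig,
    current: float,
    raw_amplitude: float,
    elapsed: float,
) -> float:
    """Comfort-ramped amplitude after ``elapsed`` seconds of progress.

    Commanded changes up to ``ramp_trigger`` apply immediately; larger
    changes advance toward the command by ``ramp_step`` every
    ``ramp_interval`` (floor(elapsed/ramp_interval) whole steps).
    """
    if not config.amp_min <= raw_amplitude <= config.amp_max:
        raise ValueError("raw amplitude outside [amp_min, amp_max]")
    delta = raw_amplitude - current
    if abs(delta) <= config.ramp_trigger:
        return raw_amplitude
    steps = int(math.floor(elapsed / config.ramp_interval + 1e-12))
    move = min(abs(delta), steps * config.ramp_step)
    return current + math.copysign(move, delta)


class ClosedLoopDriver:
    """Stateful per-sample callback wiring EWMA -> PID -> ramp into the twin.

    Instances are passed to :func:`hemoloop.patient.simulate` as the ``stim``
    callback.  An audit log of (t, smoothed, error, integral, raw command,
    emitted amplitude) rows is kept for inspection.
    """

    def __init__(self, config: ControllerConfig, initial_amplitude: float = 0.0):
        self.config = config
        self.state = ControllerState(
            last_command=initial_amplitude, emitted=initial_amplitude
        )
        self.buffer: list[float] = []
        self._last_update: Optional[float] = None
        self._last_call: Optional[float] = None
        self.log: list[tuple[float, float, float, float, float, float]] = []

    def __call__(self, t: float, sbp_measured: float) -> float:
        cfg = self.config
        elapsed = cfg.control_period if self._last_call is None else t - self._last_call
        self._last_call = t
        self.buffer.append(float(sbp_measured))
        max_len = max(1, int(round(cfg.ewma_window)) * 64)
        if len(self.buffer) > max_len:
            del self.buffer[: len(self.buffer) - max_len]
        due = self._last_update is None or t - self._last_update >= cfg.control_period - 1e-9
        if due:
            smoothed = ewma_smooth(
                self.buffer, cfg.ewma_window, cfg.ewma_forget,
                fs=1.0, mode=cfg.ewma_mode,
            )
            raw, self.state = pid_step(cfg, self.state, smoothed, cfg.control_period)
            self._last_update = t
        else:
            smoothed = float("nan")
            raw = self.state.last_command
        emitted = ramp_output(cfg, self.state.emitted, raw, elapsed)
        self.state = replace(self.state, emitted=emitted)
        self.log.append(
            (t, smoothed, self.state.previous_error, self.state.integral, raw, emitted)
        )
        return emitted

    def log_array(self) -> np.ndarray:
        return np.array(self.log)


def run_closed_loop(
    params: PatientParams,
    protocol: TiltProtocol,
    config: ControllerConfig,
    duration: float,
    seed: Optional[int] = None,
    dt: float = 1.0,
    initial_amplitude: float = 0.0,
    driver: Optional[ClosedLoopDriver] = None,
) -> BPTimeSeries:
    """Simulate the twin under closed-loop PID control of EES amplitude."""
    if config.control_period + 1e-12 < dt:
        raise ValueError("control_period must be >= simulator dt")
    if driver is None:
        driver = ClosedLoopDriver(config, initial_amplitude=initial_amplitude)
    return _patient.simulate(params, protocol, driver, duration, dt=dt, seed=seed)


def run_continuous(
    params: PatientParams,
    protocol: TiltProtocol,
    amplitude: float,
    duration: float,
    seed: Optional[int] = None,
    dt: float = 1.0,
) -> BPTimeSeries:
    """Simulate the twin under constant-amplitude (continuous) stimulation."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0 mA")
    return _patient.simulate(params, protocol, float(amplitude), duration, dt=dt, seed=seed)


# ---------------------------------------------------------------------------
# IMU-based position controller


def angle_from_accel(
    accel: Sequence[float], reference: Sequence[float] = (0.0, 0.0, 1.0)
) -> float:
    """Tilt angle (deg) between a 3D accelerometer gravity vector and the
    supine reference axis, from the arccosine of the normalized dot product."""
    a = np.asarray(accel, dtype=float)
    r = np.asarray(reference, dtype=float)
    na, nr = np.linalg.norm(a), np.linalg.norm(r)
    if na == 0 or nr == 0:
        raise ValueError("zero-magnitude vector")
    c = float(np.clip(np.dot(a, r) / (na * nr), -1.0, 1.0))
    return math.degrees(math.acos(c))


@dataclass(frozen=True)
class PositionMap:
    """Contiguous tilt-angle bands mapped to position labels and amplitudes.

    Bands are half-open [low, high) except the final band, which is closed
    at its upper edge; together they must cover [0, 90] deg.
    """

    bands: tuple[tuple[float, float, str, float], ...]

    def __post_init__(self) -> None:
        bands = tuple(self.bands)
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise ValueError("position map needs at least one band")
        if bands[0][0] != 0.0 or bands[-1][1] != 90.0:
            raise ValueError("bands must cover [0, 90] deg")
        for (l1, h1, _, a1), (l2, _h2, _, _a2) in zip(bands, bands[1:]):
            if h1 != l2:
                raise ValueError("bands must be contiguous and non-overlapping")
        for low, high, label, amp in bands:
            if low >= high:
                raise ValueError("band bounds must satisfy low < high")
            if amp < 0:
                raise ValueError("band amplitude must be >= 0 mA")

    def amplitude_for(self, angle: float) -> float:
        if not 0 <= angle <= 90:
            raise ValueError(f"angle {angle} outside the mapped range [0, 90]")
        for low, high, _label, amp in self.bands:
            if low <= angle < high:
                return amp
        return self.bands[-1][3]  # angle == 90, final band closed above

    def label_for(self, angle: float) -> str:
        for low, high, label, _amp in self.bands:
            if low <= angle < high:
                return label
        return self.bands[-1][2]

    @classmethod
    def default(cls, seated_amplitude: float, standing_amplitude: float) -> "PositionMap":
        return cls((
            (0.0, 20.0, "supine", 0.0),
            (20.0, 60.0, "seated", seated_amplitude),
            (60.0, 90.0, "standing", standing_amplitude),
        ))


class _IMUDriver:
    """Per-sample callback: noisy accelerometer -> angle -> band amplitude -> ramp."""

    def __init__(
        self,
        pos_map: PositionMap,
        config: ControllerConfig,
        protocol: TiltProtocol,
        rng: np.random.Generator,
        accel_noise_sd: float,
    ):
        self.map = pos_map
        self.config = config
        self.protocol = protocol
        self.rng = rng
        self.noise_sd = accel_noise_sd
        self.emitted = 0.0
        self._last_call: Optional[float] = None

    def __call__(self, t: float, _sbp: float) -> float:
        elapsed = (
            self.config.control_period if self._last_call is None else t - self._last_call
        )
        self._last_call = t
        theta = math.radians(self.protocol.angle_at(t))
        accel = np.array([math.sin(theta), 0.0, math.cos(theta)])
        if self.noise_sd > 0:
            accel = accel + self.rng.normal(0.0, self.noise_sd, size=3)
        ang = min(90.0, angle_from_accel(accel))
        raw = self.map.amplitude_for(ang)
        raw = min(max(raw, self.config.amp_min), self.config.amp_max)
        self.emitted = ramp_output(self.config, self.emitted, raw, elapsed)
        return self.emitted


def run_imu_loop(
    params: PatientParams,
    protocol: TiltProtocol,
    pos_map: PositionMap,
    duration: float,
    seed: Optional[int] = None,
    config: Optional[ControllerConfig] = None,
    accel_noise_sd: float = 0.02,
    dt: float = 1.0,
) -> BPTimeSeries:
    """Simulate the twin under IMU position-based amplitude control.

    The tilt-table orientation drives a synthetic 3D accelerometer (unit
    gravity vector plus isotropic Gaussian noise, in g); the derived angle is
    looked up in ``pos_map`` and the band amplitude ramped in as usual.
    """
    if config is None:
        max_amp = max(b[3] for b in pos_map.bands)
        config = ControllerConfig(kp=0.0, amp_max=max(max_amp, 1.0))
    rng = np.random.default_rng(seed)
    driver = _IMUDriver(pos_map, config, protocol, rng, accel_noise_sd)
    # patient noise drawn from a child generator so accel noise stays decoupled
    return _patient.simulate(
        params, protocol, driver, duration, dt=dt,
        rng=np.random.default_rng(rng.integers(0, 2**31)),
    )
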