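"""Synthetic hemodynamic twin of an SCI patient with orthostatic hypotension.

The twin produces a 1 Hz finger-plethysmography-style stream of systolic and
diastolic pressure and heart rate, driven by a tilt protocol and an epidural
stimulation amplitude.  Two first-order states govern the dynamics:

* an orthostatic drop that relaxes toward ``orthostatic_drop_70 *
  sin(angle)/sin(70 deg)`` with time constant ``drop_time_constant`` —
  the gravitational (hydrostatic) component of orthostatic stress scales
  with the sine of the tilt angle;
* a pressor response that relaxes toward a piecewise-linear function of the
  stimulation amplitude (zero below ``amp_threshold``, slope
  ``pressor_gain`` mm Hg/mA up to ``amp_saturation``, flat beyond) with
  time constant ``response_time_constant``.

SBP(t) = sbp_baseline - drop_state(t) + pressor_state(t) + N(0, noise_sd^2).

Both states are advanced with the exact zero-order-hold discretization
``x += (1 - exp(-dt/tau)) * (setpoint - x)``, so noiseless traces match the
continuous-time exponential step response at the sample times to machine
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np
import yaml

from .protocols import StimSchedule, TiltProtocol

__all__ = [
    "PatientParams",
    "BPTimeSeries",
    "pressor_steady_state",
    "orthostatic_setpoint",
    "simulate",
]

SIN70 = math.sin(math.radians(70.0))


@dataclass(frozen=True)
class PatientParams:
    """Parameters of the synthetic twin.

    Defaults encode a severe orthostatic-hypotension phenotype: a 50 mm Hg
    systolic drop at 70 deg tilt essentially complete within 3 min, and a
    linear pressor response of 5 mm Hg per mA between 1 and 12 mA.
    """

    sbp_baseline: float = 120.0        # mm Hg, supine, no stimulation
    dbp_baseline: float = 80.0         # mm Hg (sets the pulse pressure)
    hr_baseline: float = 70.0          # bpm
    orthostatic_drop_70: float = 50.0  # mm Hg steady-state SBP drop at 70 deg
    drop_time_constant: float = 30.0   # s; >=95% of the drop realized by 180 s
    pressor_gain: float = 5.0          # mm Hg per mA in the operating range
    amp_threshold: float = 1.0         # mA, lowest amplitude with an effect
    amp_saturation: float = 12.0       # mA, plateau onset
    response_time_constant: float = 2.0  # s, pressor onset dynamics
    noise_sd: float = 2.0              # mm Hg additive Gaussian on SBP
    hr_tilt_gain: float = 15.0         # bpm orthostatic HR increment at 70 deg
    tolerance_sbp: float = 80.0        # mm Hg presyncope threshold
    tolerance_hold: float = 10.0       # s below threshold before termination

    def __post_init__(self) -> None:
        for name in (
            "sbp_baseline", "dbp_baseline", "hr_baseline", "orthostatic_drop_70",
            "drop_time_constant", "pressor_gain", "response_time_constant",
            "noise_sd", "hr_tilt_gain",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.amp_threshold < self.amp_saturation:
            raise ValueError("amp_threshold must be < amp_saturation")
        if self.sbp_baseline < self.dbp_baseline:
            raise ValueError("sbp_baseline must be >= dbp_baseline")

    @property
    def pulse_pressure(self) -> float:
        return self.sbp_baseline - self.dbp_baseline

    def to_dict(self) -> dict:
        return {
            "sbp_baseline": self.sbp_baseline,
            "dbp_baseline": self.dbp_baseline,
            "hr_baseline": self.hr_baseline,
            "orthostatic_drop_70": self.orthostatic_drop_70,
            "drop_time_constant": self.drop_time_constant,
            "pressor_gain": self.pressor_gain,
            "amp_threshold": self.amp_threshold,
            "amp_saturation": self.amp_saturation,
            "response_time_constant": self.response_time_constant,
            "noise_sd": self.noise_sd,
            "hr_tilt_gain": self.hr_tilt_gain,
            "tolerance_sbp": self.tolerance_sbp,
            "tolerance_hold": self.tolerance_hold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PatientParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class BPTimeSeries:
    """Uniformly sampled hemodynamic stream with stimulation / tilt channels."""

    time: np.ndarray       # s
    sbp: np.ndarray        # mm Hg
    dbp: np.ndarray        # mm Hg
    hr: np.ndarray         # bpm
    angle: np.ndarray      # deg
    amplitude: np.ndarray  # mA
    fs: float = 1.0        # Hz
    termination_time: Optional[float] = None  # tilt-intolerance flag, s

    def __post_init__(self) -> None:
        arrays = [self.time, self.sbp, self.dbp, self.hr, self.angle, self.amplitude]
        n = len(self.time)
        if any(len(a) != n for a in arrays):
            raise ValueError("all channels must have equal length")
        if n == 0:
            raise ValueError("empty series")
        if n > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0) or not np.allclose(steps, 1.0 / self.fs, atol=1e-9):
                raise ValueError("time must increase uniformly at 1/fs")
        if np.any(self.sbp < self.dbp):
            raise ValueError("sbp must be >= dbp sample-wise")
        if any(not np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("non-finite values in series")

    def __len__(self) -> int:
        return len(self.time)

    def channel(self, name: str) -> np.ndarray:
        if name not in ("sbp", "dbp", "hr"):
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def window_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask for samples in the half-open window [start, end)."""
        return (self.time >= start) & (self.time < end)


def pressor_steady_state(params: PatientParams, amplitude: float) -> float:
    """Steady-state SBP rise (mm Hg) evoked by a stimulation amplitude.

    Piecewise linear: 0 up to the threshold, slope ``pressor_gain`` through
    the operating range, flat above saturation.  Continuous, non-decreasing.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0 mA")
    eff = min(amplitude, params.amp_saturation) - params.amp_threshold
    return params.pressor_gain * max(0.0, eff)


def orthostatic_setpoint(params: PatientParams, angle: float) -> float:
    """Steady-state SBP drop (mm Hg) at a held tilt angle.

    Scales the configured 70-degree drop by sin(angle)/sin(70 deg), the
    gravitational component of hydrostatic stress.
    """
    if not 0 <= angle <= 90:
        raise ValueError(f"angle must be in [0, 90] deg, got {angle}")
    return params.orthostatic_drop_70 * math.sin(math.radians(angle)) / SIN70


StimInput = Union[StimSchedule, float, Callable[[float, float], float]]


def _stim_fn(stim: StimInput) -> Callable[[float, float], float]:
    if isinstance(stim, StimSchedule):
        return lambda t, _sbp: stim.amplitude_at(t)
    if callable(stim):
        return stim  # type: ignore[return-value]
    amp = float(stim)
    if amp < 0:
        raise ValueError("constant amplitude must be >= 0 mA")
    return lambda _t, _sbp: amp


def simulate(
    params: PatientParams,
    protocol: TiltProtocol,
    stim: StimInput,
    duration: float,
    dt: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> BPTimeSeries:
    """Run the twin for ``duration`` seconds and return the 1/dt Hz stream.

    ``stim`` may be a :class:`StimSchedule`, a constant amplitude (mA), or a
    callback ``f(t, measured_sbp) -> amplitude`` invoked once per sample —
    the hook closed-loop controllers attach to.  The measured SBP passed to
    the callback includes the sensor noise.

    The twin starts at the supine equilibrium of the first protocol sample.
    A tilt-termination time is flagged (not enacted) when the measured SBP
    stays below ``tolerance_sbp`` for ``tolerance_hold`` seconds while the
    table is tilted.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    if rng is None:
        rng = np.random.default_rng(seed)
    stim_fn = _stim_fn(stim)

    n = int(round(duration / dt))
    alpha_drop = 1.0 - math.exp(-dt / params.drop_time_constant) if params.drop_time_constant > 0 else 1.0
    alpha_press = 1.0 - math.exp(-dt / params.response_time_constant) if params.response_time_constant > 0 else 1.0

    time = np.arange(n) * dt
    sbp = np.empty(n)
    angle = np.empty(n)
    amplitude = np.empty(n)

    a0 = protocol.angle_at(0.0)
    drop_state = orthostatic_setpoint(params, a0)
    amp_prev = stim_fn(0.0, params.sbp_baseline)
    pressor_state = pressor_steady_state(params, amp_prev)

    termination: Optional[float] = None
    below_since: Optional[float] = None

    for i in range(n):
        t = time[i]
        ang = protocol.angle_at(t)
        sbp_true = params.sbp_baseline - drop_state + pressor_state
        noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        sbp_meas = sbp_true + noise
        amp = float(stim_fn(t, sbp_meas))
        if not np.isfinite(amp) or not np.isfinite(sbp_meas):
            raise FloatingPointError(f"non-finite state at t={t}")

        sbp[i] = sbp_meas
        angle[i] = ang
        amplitude[i] = amp

        if termination is None and ang > 0 and sbp_meas < params.tolerance_sbp:
            if below_since is None:
                below_since = t
            if t - below_since + dt >= params.tolerance_hold:
                termination = t
        elif termination is None:
            below_since = None

        # zero-order-hold exact update toward current setpoints
        drop_state += alpha_drop * (orthostatic_setpoint(params, ang) - drop_state)
        pressor_state += alpha_press * (pressor_steady_state(params, amp) - pressor_state)

    dbp = sbp - params.pulse_pressure
    hr = params.hr_baseline + params.hr_tilt_gain * np.sin(np.radians(angle)) / SIN70
    return BPTimeSeries(
        time=time, sbp=sbp, dbp=dbp, hr=hr, angle=angle, amplitude=amplitude,
        fs=1.0 / dt, termination_time=termination,
    )
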