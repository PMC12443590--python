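# Methods

This note defines the synthetic hemodynamic model, the control chain, the
analysis metrics and the numerical conventions used throughout `hemoloop`.

## 1. Synthetic patient twin

State, sampled at `dt` (default 1 s):

```
SBP(t)  = sbp_baseline − drop(t) + pressor(t) + ε,   ε ~ N(0, noise_sd²)
DBP(t)  = SBP(t) − (sbp_baseline − dbp_baseline)     (fixed pulse pressure)
HR(t)   = hr_baseline + hr_tilt_gain · sin θ(t) / sin 70°
```

`drop` and `pressor` are first-order states advanced with the exact
zero-order-hold update `x ← x + (1 − e^(−dt/τ)) (x_setpoint − x)`, so sampled
trajectories match the continuous-time exponentials to machine precision
regardless of `dt`.

- **Orthostatic drop.** Setpoint `orthostatic_drop_70 · sin θ / sin 70°`
  (50 mm Hg at 70° by default), time constant `drop_time_constant = 30 s`.
  The sine scaling reflects the gravitationally effective component of the
  venous column along the body axis.
- **Pressor response.** Steady state is piecewise linear in stimulation
  amplitude: zero below `amp_threshold` (1 mA), slope `pressor_gain`
  (5 mm Hg/mA) up to `amp_saturation` (12 mA), flat beyond. Dynamics are
  first order with `response_time_constant = 2 s`.
- **Tilt intolerance.** If SBP stays below `tolerance_sbp` (80 mm Hg) for
  `tolerance_hold` (10 s) of continuous tilted samples, the termination time
  is flagged on the trace (the simulation itself continues, so comparisons
  remain on a common time base).

Defaults are the study conditions; they are never tuned per-test.

## 2. Tilt protocols and stimulation schedules

- **Formal tilt**: supine baseline, then a hold at up to 90°; transitions are
  linear at `transition_rate` (2°/s default, so 70° verticalization takes
  35 s, under the 45-s requirement).
- **Dynamic challenge**: 8 seeded angle changes on a 10° grid in [20°, 80°],
  hold durations uniform in [60 s, 120 s], no consecutive repeats.
- **Staircase**: amplitude steps of 1 mA per minute from 0 mA, used for
  calibration. Stimulation is otherwise parameterized by frequency (120 Hz)
  and pulse width (300 µs); amplitude is the controlled variable.

## 3. Calibration

Per staircase level, mean SBP is computed over the settled part of the level
(first 30 s excluded; with a 2-s response time constant the transient is
< 10⁻⁶ of the step after 30 s). The operating range is `[amp_min, amp_max]`
where `amp_min` is the first level whose mean exceeds the 0 mA mean by
≥ 2 mm Hg and `amp_max` the last level still rising ≥ 2 mm Hg over its
predecessor. An ordinary least-squares regression of level means on
amplitude over that range (`scipy.stats.linregress`) yields the slope
(mm Hg/mA). Controller seeding inverts it dimensionally: `Kp = 1/slope`
(mA per mm Hg), `Ki = Kp/Ti` with `Ti = 30 s`, amplitude range
`[0, amp_max]`.

## 4. Closed-loop controller

Each 1-s control period:

1. **Smoothing.** EWMA over a trailing 3-s window with forgetting factor
   0.3: weights `(1 − 0.3)^lag`, normalized. (A classic recursive one-pole
   variant is available as `ewma_mode="recursive"`.)
2. **Deadband.** Target ± 3 mm Hg. Default semantics are a hysteresis hold:
   control stays active until the error magnitude falls below an inner band
   (0.5 mm Hg), then command and controller memory freeze (no actuation
   inside the target range) until the error leaves the deadband again.
   A literal error-zeroing variant is available as `deadband_mode="zero"`;
   it keeps the recurrence running with e = 0 inside the band, which
   produces limit cycling at the band edge in the noiseless case.
3. **PID with leaky integral.** `I ← ρI + e·dt`, `u = Kp·e + Ki·I + Kd·de/dt`,
   clipped to `[amp_min, amp_max]`. The forgetting factor ρ = 0.999 per step
   bounds the integral memory (half-life ≈ 11.5 min) while keeping the DC
   gain `Kp + Ki/(1 − ρ)` large enough that the steady-state error of the
   calibration-seeded loop lies inside the deadband.
4. **Anti-windup.** When the clipped command equals the previous command and
   sits at a range bound, the integral is multiplied by γ = 0.9.
5. **Comfort ramp.** Commanded changes larger than 0.5 mA are slewed at
   0.5 mA per 500 ms (whole elapsed intervals; smaller changes apply
   immediately).

Comparators: constant-amplitude (continuous) stimulation, and an IMU
position controller that derives tilt angle from a noisy 3-axis
accelerometer (`arccos` of the normalized dot product with the supine axis)
and maps it through contiguous angle bands (supine/seated/standing by
default) to fixed amplitudes, with the same comfort ramp.

## 5. Metrics

All analysis windows are half-open `[a, b)` over the 1-Hz sample stamps.

- **Tilt ΔBP**: mean over `[t_tilt + 170 s, t_tilt + 190 s)` (a 20-s window
  centered on the 3-minute mark) minus the 60-s pre-tilt baseline mean; for
  tilts ended before 3 min, the 20 s before tilt end are used.
- **Seated ΔBP**: 20-s window at 3 min after stimulation onset minus the
  20 s before onset (sessions ≥ 3 min only).
- **Intraoperative ΔBP**: 30-s window ending at stimulation end minus the
  30 s before start (windows may overlap for short stimulations).
- **Postprandial ΔBP**: mean of cuff readings 30–60 min (inclusive) after
  the meal minus the mean of all baseline readings.
- **Challenge errors**: signed mean, mean absolute value and sample
  (ddof = 1) standard deviation of `SBP − target` from 60 s before to 60 s
  after the challenge.
- **Tilt tolerance**: elapsed time to the intolerance criterion, censored at
  the end of the recording.

## 6. Auxiliary physiology

- **Doppler flow**: `Q = (v/2)·πD²/4` converted to mL/min (×6·10⁷); the /2
  converts centerline velocity to the cross-sectional mean of a parabolic
  profile. Total cerebral blood flow sums both internal carotid and both
  vertebral arteries (middle cerebral measures are excluded).
- **Bioimpedance volume**: `V = (L²·r_eff/R)·10⁶` mL.
- **Microneurography**: 4th-order zero-phase Butterworth band-pass
  0.3–2.0 kHz at 20 kHz sampling, full-wave rectification, leaky
  integration (τ = 0.1 s). Spike detection prescreens negative deflections
  at 3× the baseline (stimulator-off) standard deviation with a 20-ms
  refractory spacing, then applies the 4.5×SD amplitude rule to a
  matched-filter estimate of the deflection depth (template projection with
  a ±0.5 ms alignment search) and a ≥ 0.8 normalized correlation gate
  against the band-pass-filtered triphasic template. The template is a 5-ms
  three-lobe half-sine (0.5 : −1 : 0.5); a substantially longer triphasic
  waveform would fall below the acquisition band-pass and be undetectable
  by construction.
- **ADFSCI hypotension section**: seven items on a 0–4 scale; the score is
  their sum and an item is symptomatic at ≥ 2.

## 7. Lead coverage

Segment lengths are modeled as independent normals, so the combined length
is `N(Σμ, Σσ²)` and the lead length covering a population fraction `c` is
`Σμ + z(c)·√(Σσ²)` with `z` the standard normal quantile.

## 8. Numerical and reproducibility conventions

- All randomness flows from `numpy.random.default_rng(seed)`; derived seeds
  are drawn as integers below 2³¹. Identical seeds give byte-identical CSV
  (`%.6f` floats, `\n` line endings) and JSON (sorted keys) outputs.
- The simulator records the measured (noisy) SBP that the controller saw,
  advances states after recording, and propagates controller exceptions.
- Validation is eager and specific: malformed traces report the offending
  column and line; configuration invariants are checked at construction.

## 9. Limitations

The twin is a deliberately low-order surrogate: it omits baroreflex
dynamics, heart-rate/pressure coupling, respiratory and circadian
variability, electrode habituation and day-to-day gain drift. Metrics and
controller behavior are therefore best read as properties of the control
stack, not as clinical predictions.
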