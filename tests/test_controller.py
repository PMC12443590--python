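import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hemoloop.controller import (
    ClosedLoopDriver,
    ControllerConfig,
    ControllerState,
    PositionMap,
    angle_from_accel,
    ewma_smooth,
    pid_step,
    ramp_output,
    run_closed_loop,
    run_continuous,
    run_imu_loop,
)
from hemoloop.patient import PatientParams
from hemoloop.protocols import make_dynamic_tilt, make_formal_tilt, with_padding


def ewma_oracle(samples, window, forget, fs=1.0):
    """Independent brute-force EWMA: explicit weight loop, no vectorization."""
    n = max(1, int(round(window * fs)))
    tail = list(samples)[-n:]
    num = den = 0.0
    for lag, x in enumerate(reversed(tail)):
        w = (1.0 - forget) ** lag
        num += w * x
        den += w
    return num / den


class TestEwma:
    def test_worked_example(self):
        # weights 1, 0.7, 0.49 on samples 120, 110, 100
        expected = (120 + 0.7 * 110 + 0.49 * 100) / (1 + 0.7 + 0.49)
        assert ewma_smooth([100, 110, 120]) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_is_identity(self):
        assert ewma_smooth([107.5] * 10) == pytest.approx(107.5)

    def test_window_truncates_history(self):
        # samples older than the window must not influence the result
        assert ewma_smooth([0, 0, 100, 110, 120], window=3) == ewma_smooth(
            [100, 110, 120], window=3
        )

    def test_short_buffer_uses_what_exists(self):
        assert ewma_smooth([118.0]) == 118.0

    @given(
        samples=st.lists(st.floats(60, 200), min_size=1, max_size=40),
        window=st.floats(1, 10),
        forget=st.floats(0.05, 0.95),
    )
    def test_matches_brute_force_oracle(self, samples, window, forget):
        got = ewma_smooth(samples, window, forget)
        assert got == pytest.approx(ewma_oracle(samples, window, forget), abs=1e-9)

    @given(samples=st.lists(st.floats(60, 200), min_size=1, max_size=20))
    def test_bounded_by_sample_range(self, samples):
        y = ewma_smooth(samples)
        assert min(samples) - 1e-9 <= y <= max(samples) + 1e-9

    def test_recursive_mode_single_pole(self):
        # y = 0.3*x + 0.7*y over [100, 110, 120]
        y = 100.0
        for x in (110.0, 120.0):
            y = 0.3 * x + 0.7 * y
        assert ewma_smooth([100, 110, 120], mode="recursive") == pytest.approx(y)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ewma_smooth([])


def pid_oracle(config, sbp_sequence, dt=1.0):
    """Scalar transcription of the PID recurrence (zero-mode deadband),
    written independently of the implementation."""
    I = 0.0
    e_prev = 0.0
    last = 0.0
    out = []
    for s in sbp_sequence:
        e = config.target - s
        if abs(e) <= config.deadband:
            e = 0.0
        I = config.integral_forget * I + e * dt
        d = (e - e_prev) / dt
        u = config.kp * e + config.ki * I + config.kd * d
        cmd = u
        if cmd < config.amp_min:
            cmd = config.amp_min
        if cmd > config.amp_max:
            cmd = config.amp_max
        if cmd == last and (cmd == config.amp_min or cmd == config.amp_max):
            I = I * config.windup_penalty
        e_prev = e
        last = cmd
        out.append(cmd)
    return out


class TestPidStep:
    def test_matches_scalar_oracle_on_random_streams(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            cfg = ControllerConfig(
                kp=float(rng.uniform(0.05, 2.0)),
                ki=float(rng.uniform(0.0, 0.1)),
                kd=float(rng.uniform(0.0, 0.5)),
                target=float(rng.uniform(100, 140)),
                deadband=float(rng.uniform(0, 5)),
                integral_forget=float(rng.uniform(0.9, 1.0)),
                windup_penalty=float(rng.uniform(0.5, 1.0)),
                amp_max=float(rng.uniform(5, 15)),
                deadband_mode="zero",
            )
            sbp = rng.uniform(60, 200, size=50)
            state = ControllerState()
            for i, s in enumerate(sbp):
                cmd, state = pid_step(cfg, state, float(s), 1.0)
                expected = pid_oracle(cfg, sbp[: i + 1])[-1]
                assert cmd == pytest.approx(expected, abs=1e-9)

    def test_proportional_only_step(self):
        cfg = ControllerConfig(kp=0.5, deadband=0.0)
        cmd, _ = pid_step(cfg, ControllerState(), 110.0, 1.0)
        assert cmd == pytest.approx(0.5 * 10.0)

    def test_command_always_within_range(self):
        cfg = ControllerConfig(kp=100.0, amp_min=0.0, amp_max=12.0, deadband=0.0)
        st_ = ControllerState()
        for s in (60.0, 200.0, 120.0):
            cmd, st_ = pid_step(cfg, st_, s, 1.0)
            assert 0.0 <= cmd <= 12.0

    def test_windup_penalty_shrinks_integral_at_bound(self):
        cfg = ControllerConfig(kp=0.1, ki=1.0, amp_max=1.0, deadband=0.0,
                               windup_penalty=0.5, deadband_mode="zero")
        st_ = ControllerState()
        for _ in range(5):
            cmd, st_ = pid_step(cfg, st_, 60.0, 1.0)  # huge persistent error
        assert cmd == 1.0
        # compare to gamma=1: integral must be strictly smaller
        cfg1 = ControllerConfig(kp=0.1, ki=1.0, amp_max=1.0, deadband=0.0,
                                windup_penalty=1.0, deadband_mode="zero")
        st1 = ControllerState()
        for _ in range(5):
            _, st1 = pid_step(cfg1, st1, 60.0, 1.0)
        assert st_.integral < st1.integral

    def test_hold_mode_freezes_inside_band(self):
        cfg = ControllerConfig(kp=0.5, ki=0.05, target=120.0)
        st_ = ControllerState()
        # drive with a real error, then return to target
        cmd, st_ = pid_step(cfg, st_, 110.0, 1.0)
        assert st_.active
        cmd_at_target, st_ = pid_step(cfg, st_, 120.0, 1.0)  # |e| <= inner band
        assert not st_.active
        frozen = st_
        cmd2, st_ = pid_step(cfg, st_, 121.0, 1.0)  # still inside deadband
        assert cmd2 == cmd_at_target
        assert st_.integral == frozen.integral
        # leaving the deadband reactivates control
        cmd3, st_ = pid_step(cfg, st_, 113.0, 1.0)
        assert st_.active
        assert cmd3 != cmd_at_target

    def test_nonfinite_input_rejected(self):
        cfg = ControllerConfig(kp=0.5)
        with pytest.raises(ValueError):
            pid_step(cfg, ControllerState(), float("nan"), 1.0)
        with pytest.raises(ValueError):
            pid_step(cfg, ControllerState(), 120.0, 0.0)


class TestRamp:
    CFG = ControllerConfig(kp=0.2, amp_max=12.0)

    def test_small_change_applies_immediately(self):
        assert ramp_output(self.CFG, 2.0, 2.4, 0.0) == 2.4

    def test_large_change_steps_half_ma_per_half_second(self):
        # 2.0 -> 4.0 mA: 0.5 mA per elapsed 0.5 s
        assert ramp_output(self.CFG, 2.0, 4.0, 0.5) == pytest.approx(2.5)
        assert ramp_output(self.CFG, 2.0, 4.0, 1.0) == pytest.approx(3.0)
        assert ramp_output(self.CFG, 2.0, 4.0, 2.0) == pytest.approx(4.0)
        assert ramp_output(self.CFG, 2.0, 4.0, 10.0) == pytest.approx(4.0)  # no overshoot

    def test_downward_changes_also_ramped(self):
        assert ramp_output(self.CFG, 4.0, 2.0, 0.5) == pytest.approx(3.5)

    def test_no_whole_step_elapsed_means_no_move(self):
        assert ramp_output(self.CFG, 2.0, 4.0, 0.25) == 2.0

    def test_out_of_range_command_rejected(self):
        with pytest.raises(ValueError):
            ramp_output(self.CFG, 2.0, 13.0, 1.0)

    @given(
        current=st.floats(0, 12), target=st.floats(0, 12), elapsed=st.floats(0, 30)
    )
    def test_rate_never_exceeded(self, current, target, elapsed):
        out = ramp_output(self.CFG, current, target, elapsed)
        steps = math.floor(elapsed / self.CFG.ramp_interval + 1e-12)
        limit = max(self.CFG.ramp_trigger, steps * self.CFG.ramp_step)
        assert abs(out - current) <= limit + 1e-9


class TestClosedLoopDriver:
    def test_emitted_respects_comfort_ramp(self, quiet_patient, default_config):
        prot = make_formal_tilt(70, 60, 600)
        drv = ClosedLoopDriver(default_config)
        run_closed_loop(quiet_patient, prot, default_config, 660, seed=0, driver=drv)
        log = drv.log_array()
        t, emitted = log[:, 0], log[:, 5]
        dt = np.diff(t)
        move = np.abs(np.diff(emitted))
        pos = dt > 0  # the simulator primes the callback once at t=0
        assert np.all(move[~pos] == 0.0)
        rate = move[pos] / dt[pos]
        assert np.all(rate <= default_config.ramp_step / default_config.ramp_interval + 1e-9)

    def test_emitted_within_amplitude_range(self, default_config):
        p = PatientParams(noise_sd=2.0)
        prot = make_formal_tilt(70, 60, 600)
        drv = ClosedLoopDriver(default_config)
        tr = run_closed_loop(p, prot, default_config, 660, seed=3, driver=drv)
        assert np.all(tr.amplitude >= default_config.amp_min)
        assert np.all(tr.amplitude <= default_config.amp_max)

    def test_noiseless_regulation_into_deadband(self, quiet_patient, default_config):
        prot = make_formal_tilt(70, 60, 1200)
        tr = run_closed_loop(quiet_patient, prot, default_config, 1260, seed=0)
        tail = tr.window_mask(960, 1260)
        err = np.abs(tr.sbp[tail] - default_config.target)
        assert np.max(err) <= default_config.deadband

    def test_determinism(self, default_config):
        p = PatientParams(noise_sd=2.0)
        prot = make_formal_tilt(70, 60, 300)
        a = run_closed_loop(p, prot, default_config, 360, seed=11)
        b = run_closed_loop(p, prot, default_config, 360, seed=11)
        assert np.array_equal(a.sbp, b.sbp)
        assert np.array_equal(a.amplitude, b.amplitude)

    def test_supine_baseline_needs_no_stimulation(self, quiet_patient, default_config):
        prot = make_formal_tilt(0, 60, 240)
        tr = run_closed_loop(quiet_patient, prot, default_config, 300, seed=0)
        assert np.all(tr.amplitude == 0.0)


class TestContinuousComparator:
    def test_constant_amplitude_recorded(self, quiet_patient):
        prot = make_formal_tilt(70, 60, 120)
        tr = run_continuous(quiet_patient, prot, 6.0, 180, seed=0)
        assert np.all(tr.amplitude == 6.0)

    def test_negative_amplitude_rejected(self, quiet_patient):
        with pytest.raises(ValueError):
            run_continuous(quiet_patient, make_formal_tilt(70, 60, 60), -1.0, 120)


class TestImuController:
    def test_angle_from_accel_examples(self):
        assert angle_from_accel((0, 0, 1)) == pytest.approx(0.0)
        assert angle_from_accel((1, 0, 0)) == pytest.approx(90.0)
        th = math.radians(70)
        assert angle_from_accel((math.sin(th), 0, math.cos(th))) == pytest.approx(70.0)

    def test_angle_scale_invariant(self):
        assert angle_from_accel((0.5, 0, 0.5)) == pytest.approx(45.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_from_accel((0, 0, 0))

    def test_position_map_lookup(self):
        m = PositionMap.default(3.0, 6.0)
        assert m.amplitude_for(0.0) == 0.0
        assert m.amplitude_for(19.99) == 0.0
        assert m.amplitude_for(20.0) == 3.0
        assert m.amplitude_for(60.0) == 6.0
        assert m.amplitude_for(90.0) == 6.0
        assert m.label_for(45.0) == "seated"

    def test_position_map_validation(self):
        with pytest.raises(ValueError):
            PositionMap(((0.0, 30.0, "supine", 0.0), (40.0, 90.0, "up", 5.0)))
        with pytest.raises(ValueError):
            PositionMap(((10.0, 90.0, "up", 5.0),))

    def test_imu_loop_switches_amplitude_with_position(self, quiet_patient):
        prot = with_padding(make_dynamic_tilt(seed=4), 60, 60)
        m = PositionMap.default(3.0, 6.0)
        tr = run_imu_loop(quiet_patient, prot, m, prot.duration, seed=4,
                          accel_noise_sd=0.0)
        # supine padding gets 0 mA; tilted segments get a band amplitude
        assert tr.amplitude[30] == 0.0
        assert np.max(tr.amplitude) in (3.0, 6.0)

    def test_imu_loop_deterministic(self):
        p = PatientParams(noise_sd=2.0)
        prot = with_padding(make_dynamic_tilt(seed=9), 60, 60)
        m = PositionMap.default(3.0, 6.0)
        a = run_imu_loop(p, prot, m, prot.duration, seed=9)
        b = run_imu_loop(p, prot, m, prot.duration, seed=9)
        assert np.array_equal(a.sbp, b.sbp)
        assert np.array_equal(a.amplitude, b.amplitude)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kp=0.2, integral_forget=0.0),
            dict(kp=0.2, windup_penalty=1.5),
            dict(kp=0.2, amp_min=5.0, amp_max=5.0),
            dict(kp=0.2, ewma_forget=1.0),
            dict(kp=0.2, deadband=-1.0),
            dict(kp=0.2, deadband_mode="off"),
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ControllerConfig(**kwargs)

    def test_gamma_one_allowed(self):
        assert ControllerConfig(kp=0.2, windup_penalty=1.0).windup_penalty == 1.0

    def test_yaml_round_trip(self, tmp_path, default_config):
        path = tmp_path / "cfg.yaml"
        default_config.to_yaml(path)
        assert ControllerConfig.from_yaml(path) == default_config
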