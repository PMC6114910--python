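"""Tests of the swimming kinematics and energetics metrics."""

import numpy as np
import pytest

from lampsim.fixtures import (WaveSpec, analytic_curvature,
                              make_activation_pattern, make_traveling_wave)
from lampsim.metrics import (KinematicsSeries, MetricsReport, body_wavelength,
                             cost_of_transport, duty_cycle, phase_lag_profile,
                             strouhal, swimming_speed, tailbeat_metrics,
                             wave_speeds)

L = 12.56


def straight_series(speed_cm_s: float, duration=10.0, dt=0.01):
    t = np.arange(0.0, duration + dt / 2, dt)
    s = np.linspace(0, L, 65)
    x = s[None, :] - speed_cm_s * t[:, None]
    y = np.zeros_like(x)
    return KinematicsSeries(t, np.stack([x, y], axis=-1), L)


class TestSwimmingSpeed:
    def test_stationary_body(self):
        assert swimming_speed(straight_series(0.0)) == 0.0

    def test_uniform_drift(self):
        # 6.53 cm/s over L = 12.56 cm is 0.52 L/s (the control-case scale)
        assert swimming_speed(straight_series(6.53)) == pytest.approx(
            6.53 / L, rel=1e-9)
        assert swimming_speed(straight_series(6.53)) == pytest.approx(
            0.52, abs=0.0002)

    def test_window_not_covered_raises(self):
        with pytest.raises(ValueError):
            swimming_speed(straight_series(1.0, duration=4.0))


class TestTailbeatMetrics:
    def test_pure_sinusoid(self):
        t = np.arange(0, 10, 0.005)
        a, f = 1.3, 0.9
        pos = np.zeros((t.size, 5, 2))
        pos[:, -1, 1] = a * np.sin(2 * np.pi * f * t)
        amp, freq = tailbeat_metrics(KinematicsSeries(t, pos, L))
        assert amp == pytest.approx(a / L, rel=1e-2)
        assert freq == pytest.approx(f, rel=1e-3)

    def test_linear_drift_invariance(self):
        t = np.arange(0, 10, 0.005)
        pos = np.zeros((t.size, 5, 2))
        pos[:, -1, 1] = 0.8 * np.sin(2 * np.pi * 1.1 * t) + 0.3 * t
        amp, freq = tailbeat_metrics(KinematicsSeries(t, pos, L))
        assert freq == pytest.approx(1.1, rel=1e-3)
        assert amp == pytest.approx(0.8 / L, rel=5e-3)

    def test_two_harmonic_signal_recovers_fundamental(self):
        t = np.arange(0, 12, 0.004)
        y = np.sin(2 * np.pi * 1.0 * t) + 0.25 * np.sin(2 * np.pi * 2.0 * t)
        pos = np.zeros((t.size, 3, 2))
        pos[:, -1, 1] = y
        _, freq = tailbeat_metrics(KinematicsSeries(t, pos, L))
        assert freq == pytest.approx(1.0, rel=1e-2)

    def test_too_few_cycles_raises(self):
        t = np.arange(0, 2.0, 0.01)
        pos = np.zeros((t.size, 3, 2))
        pos[:, -1, 1] = np.sin(2 * np.pi * 1.0 * t)
        with pytest.raises(ValueError):
            tailbeat_metrics(KinematicsSeries(t, pos, L))


class TestDutyCycle:
    def test_always_on_is_unity(self):
        t = np.arange(0, 10, 0.01)
        sigma = np.ones((t.size, 4), dtype=np.int8)
        assert duty_cycle(t, sigma) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("duty", [0.25, 0.36, 0.6])
    def test_square_wave(self, duty):
        t = np.arange(0, 10, 0.001)
        sigma = ((t[:, None] % 1.0) < duty).astype(np.int8)
        assert duty_cycle(t, sigma) == pytest.approx(duty, abs=2e-3)

    def test_no_activity_raises(self):
        t = np.arange(0, 5, 0.01)
        with pytest.raises(ValueError):
            duty_cycle(t, np.zeros((t.size, 3), dtype=np.int8))


class TestPhaseLag:
    def test_onset_at_peak_gives_zero(self):
        spec = WaveSpec(duration=8.0, n_s=33)
        t = np.arange(0.0, 8.0 + 0.005, 0.01)
        s = np.linspace(0, 1, 33)
        kappa = analytic_curvature(spec, t, s)
        sigma = make_activation_pattern(spec, 0.36, lambda q: 0.0 * q, t, s)
        phi = phase_lag_profile(t, kappa, sigma)
        assert np.nanmax(np.abs(phi)) < 0.02

    def test_constant_offset_recovered(self):
        spec = WaveSpec(duration=8.0, n_s=33)
        t = np.arange(0.0, 8.0 + 0.005, 0.01)
        s = np.linspace(0, 1, 33)
        kappa = analytic_curvature(spec, t, s)
        sigma = make_activation_pattern(spec, 0.36, lambda q: 0.1 + 0 * q, t, s)
        phi = phase_lag_profile(t, kappa, sigma)
        assert np.nanmean(phi) == pytest.approx(0.1, abs=0.02)

    def test_linear_profile_recovered_within_sample(self):
        spec = WaveSpec(duration=8.0, n_s=33)
        dt = 0.01
        t = np.arange(0.0, 8.0 + dt / 2, dt)
        s = np.linspace(0, 1, 33)
        kappa = analytic_curvature(spec, t, s)
        lag = lambda q: 0.05 + 0.15 * q
        sigma = make_activation_pattern(spec, 0.36, lag, t, s)
        phi = phase_lag_profile(t, kappa, sigma)
        ok = ~np.isnan(phi)
        assert np.all(np.abs(phi[ok] - lag(s[ok])) < dt / 1.0 + 0.02)


class TestWaveSpeeds:
    def test_linear_phase_activation_speed(self):
        # θ = ωt − (2π/Λ)s  ⇒  v_a = ωΛ/2π
        t = np.arange(0, 6, 0.01)
        s = np.linspace(0, 10, 41)
        om, lam = 2 * np.pi, 7.0
        theta = om * t[:, None] - (2 * np.pi / lam) * s[None, :]
        kappa = np.cos(theta)
        va, V, ratio = wave_speeds(t, s, theta, kappa)
        assert va == pytest.approx(om * lam / (2 * np.pi), rel=1e-6)

    def test_hilbert_speed_on_traveling_wave(self):
        # κ = cos(2π(t − s/c)): curvature wave speed V = c within 1%
        t = np.arange(0, 8, 0.01)
        s = np.linspace(0, 10, 81)
        c = 5.5
        kappa = np.cos(2 * np.pi * (t[:, None] - s[None, :] / c))
        theta = 2 * np.pi * (t[:, None] - s[None, :] / c)
        va, V, ratio = wave_speeds(t, s, theta, kappa)
        assert V == pytest.approx(c, rel=0.01)

    def test_identical_waves_ratio_one(self):
        t = np.arange(0, 8, 0.01)
        s = np.linspace(0, 10, 81)
        theta = 2 * np.pi * (t[:, None] - s[None, :] / 6.0)
        va, V, ratio = wave_speeds(t, s, theta, np.cos(theta))
        assert ratio == pytest.approx(1.0, rel=0.01)

    def test_scale_invariance_of_curvature_speed(self):
        # V is a phase quantity: rescaling κ leaves it unchanged
        t = np.arange(0, 8, 0.01)
        s = np.linspace(0, 10, 81)
        theta = 2 * np.pi * (t[:, None] - s[None, :] / 6.0)
        kap = np.cos(theta)
        _, V1, _ = wave_speeds(t, s, theta, kap)
        _, V2, _ = wave_speeds(t, s, theta, 17.3 * kap)
        assert V1 == pytest.approx(V2, rel=1e-9)

    def test_nonuniform_sampling_rejected(self):
        t = np.concatenate([np.arange(0, 3, 0.01), np.arange(3, 6, 0.02)])
        s = np.linspace(0, 10, 21)
        theta = t[:, None] - s[None, :]
        with pytest.raises(ValueError):
            wave_speeds(t, s, theta, np.cos(theta))


class TestStrouhal:
    def test_control_scale_value(self):
        # 2·(1 Hz)·(0.12 L)/(0.52 L/s)
        assert strouhal(1.0, 0.12, 0.52) == pytest.approx(0.4615, abs=2e-4)

    def test_zero_frequency(self):
        assert strouhal(0.0, 0.12, 0.5) == 0.0

    def test_homogeneity(self):
        assert strouhal(1.0, 0.24, 1.04) == pytest.approx(
            strouhal(1.0, 0.12, 0.52))

    def test_zero_speed_raises(self):
        with pytest.raises(ZeroDivisionError):
            strouhal(1.0, 0.1, 0.0)

    def test_report_self_consistency(self):
        rep = MetricsReport(speed=0.5, amplitude=0.1, frequency=1.2)
        rep.strouhal = strouhal(rep.frequency, rep.amplitude, rep.speed)
        assert rep.recompute_strouhal() == pytest.approx(rep.strouhal)


class TestBodyWavelength:
    def test_sinusoidal_curvature(self):
        s = np.linspace(0, 12.0, 241)
        lam = 4.8
        kappa = np.sin(2 * np.pi * s / lam)[None, :].repeat(3, axis=0)
        assert body_wavelength(s, kappa) == pytest.approx(lam, rel=1e-3)


class TestCostOfTransport:
    def test_all_positive_work(self):
        t = np.arange(0, 4, 0.001)
        power = np.ones((t.size, 3))  # 3 segments, 1 erg/s each
        cot, _ = cost_of_transport(t, power, period=1.0, mass=2.0, f_neg=0.3)
        assert cot == pytest.approx(3.0 / 2.0, rel=1e-3)

    def test_negative_work_fraction(self):
        t = np.arange(0, 4, 0.001)
        power = -np.ones((t.size, 1))
        cot_w, _ = cost_of_transport(t, power, 1.0, 1.0, f_neg=0.3)
        assert cot_w == pytest.approx(0.3, rel=1e-3)
        cot_0, _ = cost_of_transport(t, power, 1.0, 1.0, f_neg=0.0)
        assert cot_0 == pytest.approx(0.0, abs=1e-9)

    def test_control_normalizes_to_unity(self):
        t = np.arange(0, 4, 0.001)
        power = np.abs(np.sin(2 * np.pi * t))[:, None]
        cot, _ = cost_of_transport(t, power, 1.0, 1.0)
        _, norm = cost_of_transport(t, power, 1.0, 1.0, control_cot=cot)
        assert norm == pytest.approx(1.0, rel=1e-12)

    def test_missing_control_for_normalization(self):
        t = np.arange(0, 4, 0.001)
        with pytest.raises(ValueError):
            cost_of_transport(t, np.ones((t.size, 1)), 1.0, 1.0,
                              control_cot=0.0)
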