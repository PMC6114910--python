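"""Tests of the calcium kinetics, work-dependent deactivation and
Hill-type force generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lampsim.muscle import (CalciumMuscleState, MuscleBank, MuscleParams,
                            calcium_derivatives, contractile_force,
                            endpoint_forces, force_length, force_velocity,
                            rate_constants, taper_factor,
                            work_deactivation_derivative)


@pytest.fixture
def params() -> MuscleParams:
    return MuscleParams()


class TestRateConstants:
    def test_active_shuts_resequestration(self, params):
        k1, k2, k3, k4 = rate_constants(1, 1.0, params)
        assert k1 == params.kbar1
        assert k2 == 0.0

    def test_inactive_shuts_release(self, params):
        k1, k2, _, _ = rate_constants(0, 1.0, params)
        assert k1 == 0.0
        assert k2 == params.kbar2

    def test_linear_in_work_variable(self, params):
        _, _, k3a, k4a = rate_constants(1, 1.0, params)
        _, _, k3b, k4b = rate_constants(1, 2.0, params)
        assert k3b == pytest.approx(2 * k3a)
        assert k4b == pytest.approx(2 * k4a)


class TestCalciumDerivatives:
    def test_empty_inactive_state_is_fixed_point(self, params):
        dCf, dCb = calcium_derivatives(0.0, 0.0, 0, 1.0, params)
        assert dCf == 0.0 and dCb == 0.0

    def test_saturated_bound_pool_frozen(self, params):
        _, dCb = calcium_derivatives(0.4, 1.0, 1, 1.0, params)
        assert dCb == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(Cf=st.floats(0.0, 2.0), Cb=st.floats(0.0, 1.0),
           m=st.floats(0.5, 3.0), sigma=st.sampled_from([0, 1]))
    def test_conservation_without_sr_exchange(self, Cf, Cb, m, sigma):
        # with k1 = k2 = 0 the exchange terms cancel exactly: C_f + C_b
        # is a conserved quantity
        p = MuscleParams(kbar1=0.0, kbar2=0.0)
        dCf, dCb = calcium_derivatives(Cf, Cb, sigma, m, p)
        assert dCf + dCb == pytest.approx(0.0, abs=1e-12)

    def test_bound_calcium_stays_in_unit_interval(self, params):
        # integrate a full activation cycle and check the invariant
        bank = MuscleBank(np.array([0.2]), np.array([1.0]), params)
        ls = np.full((2, 1), 0.2)
        dt = 5e-4
        for i in range(4000):
            t = i * dt
            sig = np.array([[1], [0]]) if (t % 1.0) < 0.36 else np.zeros((2, 1))
            bank.step(sig, ls, dt)
            st_ = bank.state
            assert np.all(st_.Cb >= -1e-9) and np.all(st_.Cb <= 1.0 + 1e-9)
            assert np.all(st_.Cf >= -1e-9)

    def test_pool_ordering_enforced(self):
        with pytest.raises(ValueError):
            MuscleParams(Ctot=5.0, Ssites=3.0)
        with pytest.raises(ValueError):
            MuscleParams(Ctot=0.5, Ssites=3.0)


class TestWorkDeactivation:
    def test_rest_is_fixed_point(self, params):
        assert work_deactivation_derivative(1.0, 0.5, 1.0, params) == 0.0

    def test_relaxation_branch_value(self, params):
        dm = work_deactivation_derivative(1.5, 0.0, 1.0, params)
        assert dm == pytest.approx(-0.5 * params.km2)

    def test_loaded_shortening_grows_m(self, params):
        dm = work_deactivation_derivative(1.0, 0.8, -2.0, params)
        assert dm == pytest.approx(params.km1 * 0.8 * 2.0)

    def test_exponential_recovery_oracle(self, params):
        # closed form of the linear branch: m(t) = 1 + (m0−1)e^(−km2 t)
        m, dt = 2.0, 1e-4
        for _ in range(10000):
            m += dt * work_deactivation_derivative(m, 0.0, 1.0, params)
        assert m == pytest.approx(1.0 + 1.0 * np.exp(-params.km2), rel=1e-3)


class TestContractileForce:
    def test_no_calcium_no_force(self, params):
        assert contractile_force(-1.0, 1.0, 0.0, 0.7, params, lc_rest=1.0) == 0.0

    def test_normalization_at_rest(self, params):
        f = contractile_force(0.0, 1.0, 0.6, 0.8, params, lc_rest=1.0)
        assert f == pytest.approx(params.P0 * 0.6 * 0.8)

    def test_taper_scales_linearly(self, params):
        f1 = contractile_force(0.0, 1.0, 0.5, 1.0, params, lc_rest=1.0)
        f2 = contractile_force(0.0, 1.0, 0.5, 0.5, params, lc_rest=1.0)
        assert f2 == pytest.approx(0.5 * f1)

    def test_force_velocity_monotone_decreasing(self, params):
        v = np.linspace(-params.v_max, params.v_max, 201)
        a = force_velocity(v, params)
        assert np.all(np.diff(a) >= -1e-12)
        assert force_velocity(0.0, params) == pytest.approx(1.0)
        assert force_velocity(-params.v_max, params) == pytest.approx(0.0)
        assert np.all(a <= params.alpha_max + 1e-12)

    def test_force_length_peak_at_rest(self, params):
        assert force_length(1.0, 1.0, params) == pytest.approx(1.0)
        assert force_length(1.0 + params.lam_width, 1.0, params) == \
            pytest.approx(0.0, abs=1e-12)
        assert force_length(1.0 - params.lam_width, 1.0, params) == \
            pytest.approx(0.0, abs=1e-12)


class TestTaperFactor:
    def test_maximal_width_gives_one(self):
        w = np.array([0.5, 1.0, 0.25])
        assert taper_factor(w)[1] == 1.0

    def test_elliptical_area_scaling(self):
        # width half the maximum -> area ratio (1/2)^2 = 1/4
        w = np.array([0.5, 1.0])
        assert taper_factor(w)[0] == pytest.approx(0.25)


class TestMuscleBank:
    def test_inactive_at_rest_no_force(self, params):
        bank = MuscleBank(np.array([0.2, 0.2]), np.array([1.0, 0.5]), params)
        tension, Pc = bank.step(np.zeros((2, 2)), np.full((2, 2), 0.2), 1e-4)
        assert np.allclose(tension, 0.0, atol=1e-8)
        assert np.allclose(Pc, 0.0)

    def test_skin_resists_extension_only(self):
        # compare identical banks with and without skin: the skin adds
        # tension for a stretched segment and exactly nothing when the
        # segment is compressed below rest length
        p = MuscleParams(passive_ca=False)
        p0 = p.replace(k_skin=0.0)
        for ls_val, expect in ((0.24, p.k_skin * 0.04 / 0.2), (0.16, 0.0)):
            with_skin = MuscleBank(np.array([0.2]), np.array([1.0]), p)
            no_skin = MuscleBank(np.array([0.2]), np.array([1.0]), p0)
            ls = np.full((2, 1), ls_val)
            t1, _ = with_skin.step(np.zeros((2, 1)), ls, 1e-4)
            t2, _ = no_skin.step(np.zeros((2, 1)), ls, 1e-4)
            assert t1[0, 0] - t2[0, 0] == pytest.approx(expect, rel=1e-9,
                                                        abs=1e-9)

    def test_step_activation_transient_rises_and_decays(self, params):
        # isometric segment: force rises during the 0.36 s burst, peaks near
        # its end, and decays before the next burst; peak <= P0·taper
        taper = 0.8
        bank = MuscleBank(np.array([0.2]), np.array([taper]), params)
        ls = np.full((2, 1), 0.2)
        dt = 5e-4
        trace = []
        for i in range(int(3.0 / dt)):
            t = i * dt
            sig = np.array([[1], [0]]) if (t % 1.0) < 0.36 else np.zeros((2, 1))
            _, Pc = bank.step(sig, ls, dt)
            trace.append(Pc[0, 0])
        trace = np.asarray(trace)
        cycle = trace[int(2.0 / dt):]
        peak_t = np.argmax(cycle) * dt
        assert 0.2 < peak_t < 0.55            # peak near burst end
        assert cycle.max() <= params.P0 * taper + 1e-9
        assert cycle.max() > 0.5 * params.P0 * taper
        assert cycle[int(0.9 / dt)] < 0.1 * cycle.max()   # decayed

    def test_work_deactivation_speeds_force_decay(self, params):
        # shortening under load raises m, which scales the calcium exchange
        # rates: the force developed in a cycle relaxes faster after the
        # burst, lowering the post-burst and cycle-mean force relative to
        # the model with the work variable frozen (km1 = 0)
        def run(km1):
            p = params.replace(km1=km1)
            bank = MuscleBank(np.array([0.2]), np.array([1.0]), p)
            dt = 5e-4
            trace = []
            for i in range(int(3.0 / dt)):
                t = i * dt
                sig = (np.array([[1], [0]]) if (t % 1.0) < 0.36
                       else np.zeros((2, 1)))
                # imposed sinusoidal length change (shortening while active)
                ls = np.full((2, 1), 0.2 * (1 + 0.1 * np.cos(2 * np.pi * t)))
                _, Pc = bank.step(sig, ls, dt)
                trace.append(Pc[0, 0])
            cycle = np.asarray(trace[int(2.0 / dt):])
            post_burst = cycle[int(0.4 / dt):int(1.0 / dt)].mean()
            return post_burst, cycle.mean()

        post_w, mean_w = run(km1=5.0)
        post_0, mean_0 = run(km1=0.0)
        assert post_w < post_0
        assert mean_w < mean_0

    def test_endpoint_forces_equal_and_opposite(self, rng):
        n = 7
        tension = rng.normal(size=(2, n))
        p0 = rng.normal(size=(2, n, 2))
        p1 = p0 + rng.normal(size=(2, n, 2)) + 3.0
        F0, F1 = endpoint_forces(tension, p0, p1)
        assert np.allclose(F0 + F1, 0.0, atol=1e-12)
        # force is axial
        d = p1 - p0
        cross = F0[..., 0] * d[..., 1] - F0[..., 1] * d[..., 0]
        assert np.allclose(cross, 0.0, atol=1e-9)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            endpoint_forces(np.ones((1,)), np.zeros((1, 2)), np.zeros((1, 2)))
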