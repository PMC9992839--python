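"""Half-sarcomere OFF/ON model: analytic limits, oracle equivalence, domains."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import cumulative_trapezoid, solve_ivp

from titinmech.mech_model import (
    DomainError,
    ForceStepProtocol,
    MechModelError,
    TitinMechParams,
    rectifier_viscosity,
    resting_fluidity,
    simulate_off,
    simulate_on,
    stress_to_force_per_htf,
)

from conftest import ideal_protocol


class TestRestingFluidity:
    def test_linear_map_between_reference_and_contour(self, off_params):
        f27 = resting_fluidity(off_params, 2.7)
        assert f27 == pytest.approx(1e3)
        # falls to 1/3 of the 2.7 um value at 3.0 um (intercept 3.15)
        assert resting_fluidity(off_params, 3.0) == pytest.approx(f27 / 3)
        assert resting_fluidity(off_params, 3.15) == 0.0
        assert resting_fluidity(off_params, 3.5) == 0.0  # clipped beyond contour
        assert resting_fluidity(off_params, off_params.SL_ref) == pytest.approx(
            off_params.fluidity_max
        )

    def test_below_slack_length_is_a_domain_error(self, off_params):
        with pytest.raises(DomainError):
            resting_fluidity(off_params, 2.1)


class TestRectifier:
    def test_branch_selection(self, table1):
        assert rectifier_viscosity(table1[2.7], +50.0) == 6.25
        assert rectifier_viscosity(table1[3.0], -20.0) == 1.60e-3

    def test_zero_step_is_inert(self, table1):
        # branch choice at delta_T = 0 is irrelevant: no flow occurs
        assert rectifier_viscosity(table1[2.7], 0.0) == table1[2.7].eta3
        tr = simulate_on(table1[2.7], ideal_protocol(0.0, duration=0.05), 2.7)
        assert np.all(tr.x == 0.0)


class TestStressConversion:
    @pytest.mark.parametrize(
        "stress_kpa, expected_pn",
        [(144.0, 245.3), (0.0, 0.0), (72.0, 122.66)],
    )
    def test_lattice_geometry_conversion(self, stress_kpa, expected_pn):
        assert stress_to_force_per_htf(stress_kpa) == pytest.approx(
            expected_pn, abs=0.05
        )

    def test_invalid_inputs(self):
        with pytest.raises(MechModelError):
            stress_to_force_per_htf(100.0, filament_density=0.0)
        with pytest.raises(MechModelError):
            stress_to_force_per_htf(-1.0)


def _on_closed_form(params, protocol, t):
    """Independent closed-form solution of the ON circuit for a linear ramp."""
    dT, r, ts = protocol.delta_T, protocol.rise_time, protocol.t_step
    tau, eb = params.tau2, params.e_b
    eta = rectifier_viscosity(params, dT)
    x = np.zeros_like(t)
    during = (t > ts) & (t <= ts + r)
    after = t > ts + r
    u = t[during] - ts
    x[during] = (
        dT * u / (r * params.e1)
        + dT * u**2 / (2 * r * eta)
        + (dT / (eb * r)) * (u - tau * (1 - np.exp(-u / tau)))
    )
    v = t[after] - ts - r
    xkv_end = (dT / (eb * r)) * (r - tau * (1 - np.exp(-r / tau)))
    x[after] = (
        dT / params.e1
        + dT * (v + r / 2) / eta
        + dT / eb
        + (xkv_end - dT / eb) * np.exp(-v / tau)
    )
    return x


class TestSimulateOn:
    def test_matches_closed_form_oracle(self, table1):
        protocol = ForceStepProtocol(
            delta_T=50.0, rise_time=150e-6, t_step=5e-3, duration=0.05, dt=1e-5
        )
        tr = simulate_on(table1[2.7], protocol, 2.7)
        expected = _on_closed_form(table1[2.7], protocol, tr.time)
        np.testing.assert_allclose(tr.x, expected, rtol=1e-6, atol=1e-12)

    def test_matches_independent_stiff_integrator(self, table1):
        params = table1[2.7]
        protocol = ForceStepProtocol(
            delta_T=50.0, rise_time=150e-6, t_step=2e-3, duration=0.02, dt=1e-5
        )
        tr = simulate_on(params, protocol, 2.7)

        def rhs(t, y):
            f = protocol.force(np.array([t]))[0]
            return [(f - params.e_b * y[0]) / params.eta_b]

        sol = solve_ivp(
            rhs, (0, protocol.duration), [0.0], t_eval=tr.time,
            rtol=1e-10, atol=1e-13, max_step=protocol.rise_time,
        )
        f = protocol.force(tr.time)
        x_ref = (
            f / params.e1
            + sol.y[0]
            + np.concatenate(
                [[0.0], cumulative_trapezoid(f / params.eta3, tr.time)]
            )
        )
        np.testing.assert_allclose(tr.x, x_ref, atol=1e-6)

    def test_step_response_limits(self, table1):
        # +50 pN with the 2.7 um constants: late slope 8 nm/s, fast
        # amplitude (back-extrapolated) 50/3.02 = 16.56 nm
        params = table1[2.7]
        protocol = ideal_protocol(50.0)
        tr = simulate_on(params, protocol, 2.7)
        i0 = np.searchsorted(tr.time, protocol.t_end + 0.10)
        i1 = np.searchsorted(tr.time, protocol.t_end + 0.20)
        slope, intercept = np.polyfit(tr.time[i0:i1], tr.x[i0:i1], 1)
        assert slope == pytest.approx(50.0 / 6.25, rel=1e-6)
        assert slope * protocol.t_half + intercept == pytest.approx(
            50.0 / 3.02, rel=1e-6
        )
        jump = tr.x[np.searchsorted(tr.time, protocol.t_end)]
        assert jump == pytest.approx(50.0 / params.e1, rel=0.05)

    def test_shortening_exceeds_twice_unloaded_velocity(self, table1):
        # restoring force -24.9 pN at 3.0 um: steady shortening faster than
        # twice the 2,530 nm/s unloaded velocity of the motors
        protocol = ideal_protocol(-24.9, duration=0.05)
        tr = simulate_on(table1[3.0], protocol, 3.0)
        i0 = np.searchsorted(tr.time, protocol.t_end + 1e-3)
        i1 = np.searchsorted(tr.time, protocol.t_end + 5e-3)
        v = np.polyfit(tr.time[i0:i1], tr.x[i0:i1], 1)[0]
        assert v == pytest.approx(-24.9 / 1.60e-3, rel=0.01)
        assert abs(v) > 2 * 2530

    def test_rectification_ratio(self, table1):
        params = table1[3.0]
        vp = simulate_on(params, ideal_protocol(20.0, duration=0.05), 3.0)
        vn = simulate_on(params, ideal_protocol(-20.0, duration=0.05), 3.0)
        i0, i1 = 1500, 4500
        v_pos = np.polyfit(vp.time[i0:i1], vp.x[i0:i1], 1)[0]
        v_neg = np.polyfit(vn.time[i0:i1], vn.x[i0:i1], 1)[0]
        ratio = abs(v_neg) / v_pos
        assert ratio == pytest.approx(params.eta3 / params.eta_sh, rel=0.02)
        assert ratio >= 2e3

    def test_stim_end_switch_resumes_resting_extensibility(self, table1):
        params = table1[2.7]
        protocol = ForceStepProtocol(
            delta_T=50.0, rise_time=1e-5, t_step=5e-3, duration=0.4, dt=1e-5,
            stim_window=(0.0, 0.29),
        )
        tr = simulate_on(params, protocol, 2.7)
        i = np.searchsorted(tr.time, 0.29)
        assert abs(tr.x[i + 1] - tr.x[i]) < 5.0  # continuous at the switch
        v_on = np.polyfit(tr.time[i - 200 : i], tr.x[i - 200 : i], 1)[0]
        v_off = np.polyfit(tr.time[i + 1 : i + 201], tr.x[i + 1 : i + 201], 1)[0]
        assert v_off > 10 * v_on


class TestSimulateOff:
    def test_initial_velocity_follows_shifted_fluidity(self, off_params):
        # the PEVK jump raises the instantaneous SL before the Ig creep
        # starts, so the initial velocity is dT * fluidity at the shifted SL
        protocol = ideal_protocol(50.0, duration=0.01)
        tr = simulate_off(off_params, protocol, 2.7)
        sl_shifted = 2.7 + 2e-3 * 50.0 / off_params.e_pevk
        v_expected = 50.0 * resting_fluidity(off_params, sl_shifted)
        i0 = np.searchsorted(tr.time, protocol.t_end)
        i1 = np.searchsorted(tr.time, protocol.t_end + 0.5e-3)
        v = np.polyfit(tr.time[i0 : i1 + 1], tr.x[i0 : i1 + 1], 1)[0]
        assert v == pytest.approx(v_expected, rel=0.06)

    def test_velocity_self_quenches_and_respects_contour(self, off_params):
        protocol = ideal_protocol(50.0, duration=0.3)
        tr = simulate_off(off_params, protocol, 3.0)
        post = tr.x[np.searchsorted(tr.time, protocol.t_end) :]
        v = np.diff(post)
        assert np.all(np.diff(v) <= 1e-12)  # monotone non-increasing velocity
        assert np.all(post <= (3.15 - 3.0) / 2e-3 + 1e-9)

    def test_contour_length_limit_is_pure_pevk_spring(self, off_params):
        protocol = ideal_protocol(50.0, duration=0.1)
        tr = simulate_off(off_params, protocol, 3.15)
        dF = tr.force
        np.testing.assert_allclose(tr.x, dF / off_params.e_pevk, atol=1e-12)

    def test_pevk_elastic_amplitude(self, off_params):
        # +50 pN at 3.0 um: elastic component 50 * 0.65 = 32.5 nm
        protocol = ideal_protocol(50.0, duration=0.01)
        tr = simulate_off(off_params, protocol, 3.0)
        x_end = tr.x[np.searchsorted(tr.time, protocol.t_end)]
        assert x_end == pytest.approx(50.0 * 0.65, rel=0.01)

    def test_domain_errors(self, off_params):
        with pytest.raises(DomainError):
            simulate_off(off_params, ideal_protocol(50.0), 2.0)
        with pytest.raises(DomainError):
            simulate_off(off_params, ideal_protocol(50.0), 3.3)
        # a large negative step drives SL below the slack length
        with pytest.raises(DomainError):
            simulate_off(off_params, ideal_protocol(-100.0, duration=0.25), 2.5)


class TestInvariants:
    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        delta_T=st.floats(min_value=5.0, max_value=80.0),
        SL0=st.floats(min_value=2.3, max_value=3.1),
    )
    def test_length_non_decreasing_under_positive_load(self, delta_T, SL0):
        params = TitinMechParams()
        protocol = ideal_protocol(delta_T, duration=0.05)
        for tr in (
            simulate_off(params, protocol, SL0),
            simulate_on(params, protocol, SL0),
        ):
            assert np.all(np.diff(tr.x) >= -1e-12)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(MechModelError):
            TitinMechParams(e2=8.0, e1=7.0)
        with pytest.raises(MechModelError):
            TitinMechParams(eta_sh=10.0, eta3=6.0)
        with pytest.raises(MechModelError):
            TitinMechParams(SL_ref=3.2, SL_c=3.15)
        with pytest.raises(MechModelError):
            TitinMechParams(tau2=-1e-3)

    def test_protocol_invariants_enforced(self):
        with pytest.raises(MechModelError):
            ForceStepProtocol(delta_T=50.0, rise_time=-1e-4)
        with pytest.raises(MechModelError):
            ForceStepProtocol(delta_T=50.0, t_step=0.3, duration=0.25)
        p = ForceStepProtocol(delta_T=50.0, t_step=5e-3, rise_time=150e-6)
        assert p.t_half == pytest.approx(5e-3 + 75e-6)
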