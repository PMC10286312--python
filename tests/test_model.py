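"""ODE model: closed-form limits, oracle agreement, physical invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tkreceptor import ExposureScenario, TKParameters, simulate, steady_state

from conftest import euler_simulate


def one_compartment_closed_form(k_u, k_e, c_w, t):
    """C_structure(t) for a single first-order compartment from zero."""
    return k_u / k_e * c_w * (1.0 - np.exp(-k_e * np.asarray(t)))


class TestScenario:
    def test_pulse_train_structure(self):
        sc = ExposureScenario.pulses(0.2, 2.0, 3.0, 3)
        assert len(sc.intervals) == 6
        assert sc.t_end == 15.0
        assert sc.c_w(1.0) == 0.2
        assert sc.c_w(4.0) == 0.0
        assert sc.c_w(5.0) == 0.2  # start of second pulse

    @pytest.mark.parametrize(
        "intervals",
        [
            ((1.0, 2.0, 0.2),),  # does not start at zero
            ((0.0, 2.0, 0.2), (3.0, 4.0, 0.0)),  # gap
            ((0.0, 2.0, 0.2), (1.5, 4.0, 0.0)),  # overlap
            ((0.0, 0.0, 0.2),),  # empty interval
            ((0.0, 2.0, -0.1),),  # negative concentration
        ],
    )
    def test_invalid_intervals_rejected(self, intervals):
        with pytest.raises(ValueError):
            ExposureScenario(intervals)

    def test_ug_per_l_conversion(self):
        sc = ExposureScenario.from_ug_per_l([(0.0, 2.0, 50.0)])
        assert sc.intervals[0][2] == pytest.approx(0.2)  # 50 µg/L = 200 nM


class TestParameters:
    def test_negative_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            TKParameters(k_u=-1, k_e=5.2, k_on=200, B_max=25)
        with pytest.raises(ValueError):
            TKParameters(k_u=np.nan, k_e=5.2, k_on=200, B_max=25)
        with pytest.raises(ValueError):
            TKParameters(k_u=10, k_e=5, k_on=200, B_max=25, fms=1.5)

    def test_reversible_binding_is_flagged(self):
        with pytest.warns(UserWarning, match="k_off"):
            TKParameters(k_u=10, k_e=5, k_on=200, B_max=25, k_off=0.1)


class TestSimulate:
    def test_zero_exposure_zero_initial_state_stays_zero(self, ref_params):
        sc = ExposureScenario.constant(0.0, 5.0)
        traj = simulate(ref_params, sc, np.linspace(0, 5, 11))
        assert np.all(traj.c_total == 0.0)

    @pytest.mark.parametrize("kill", ["B_max", "fms"])
    def test_one_compartment_limit_matches_closed_form(self, kill):
        # removing the receptor pool (B_max=0) or its mass (fms->0)
        # reduces the system to first-order uptake/elimination
        kw = dict(k_u=10.6, k_e=5.2, k_on=200.0, B_max=25.0)
        kw["B_max" if kill == "B_max" else "fms"] = 0.0 if kill == "B_max" else 1e-12
        params = TKParameters(**kw)
        sc = ExposureScenario.constant(0.2, 2.0)
        t = np.linspace(0.01, 2.0, 40)
        traj = simulate(params, sc, t)
        expected = one_compartment_closed_form(10.6, 5.2, 0.2, t)
        np.testing.assert_allclose(traj.c_structure, expected, rtol=1e-6)
        assert traj.c_structure[-1] == pytest.approx(0.4077, abs=2e-4)

    def test_elimination_resistant_plateau(self, ref_params, pulse_scenario):
        # after depuration the structure pool is empty but the saturated
        # receptor pool remains: C_total -> fms * B_max
        traj = simulate(ref_params, pulse_scenario, [2.0, 4.0])
        assert traj.c_total[-1] == pytest.approx(0.25, rel=1e-3)
        assert traj.c_structure[-1] < 1e-4

    def test_agrees_with_explicit_euler_oracle(self, ref_params, pulse_scenario):
        times = np.array([0.5, 1.0, 2.0, 2.5, 3.0, 4.0])
        traj = simulate(ref_params, pulse_scenario, times)
        _, _, c_total_euler = euler_simulate(
            ref_params, pulse_scenario, times, dt=1e-5
        )
        np.testing.assert_allclose(traj.c_total, c_total_euler, rtol=1e-3)

    def test_total_is_structure_plus_weighted_mp(self, ref_params, pulse_scenario):
        traj = simulate(ref_params, pulse_scenario, np.linspace(0.1, 4, 20))
        np.testing.assert_allclose(
            traj.c_total,
            traj.c_structure + ref_params.fms * traj.c_mp,
            rtol=1e-12,
        )

    def test_mass_flux_consistency(self, ref_params):
        # the flux leaving the structure pool for the MP pool must equal
        # fms times the MP pool's gain; equivalently, adding k_e losses
        # back to d(C_total)/dt recovers the uptake flux k_u*C_W
        sc = ExposureScenario.constant(0.2, 2.0)
        t = np.linspace(0.2, 1.8, 500)
        traj = simulate(ref_params, sc, t)
        dt = t[1] - t[0]
        d_total = np.gradient(traj.c_total, dt)
        uptake_flux = ref_params.k_u * 0.2 - ref_params.k_e * traj.c_structure
        # np.gradient is only first-order at the array edges
        np.testing.assert_allclose(
            d_total[1:-1], uptake_flux[1:-1], rtol=5e-3, atol=1e-4
        )

    def test_initial_mp_above_capacity_rejected(self, ref_params, pulse_scenario):
        with pytest.raises(ValueError, match="B_max"):
            simulate(ref_params, pulse_scenario, [1.0], initial_state=(0.0, 26.0))

    def test_times_outside_span_rejected(self, ref_params, pulse_scenario):
        with pytest.raises(ValueError, match="span"):
            simulate(ref_params, pulse_scenario, [1.0, 99.0])

    @settings(max_examples=15, deadline=None)
    @given(
        k_u=st.floats(0.1, 100),
        k_e=st.floats(0.1, 20),
        k_on=st.floats(0.1, 200),
        b_max=st.floats(0.1, 100),
        c_w=st.floats(0.0, 20),
        c_mp0_frac=st.floats(0.0, 1.0),
    )
    def test_saturation_bound_and_monotone_irreversibility(
        self, k_u, k_e, k_on, b_max, c_w, c_mp0_frac
    ):
        # C_MP never exceeds B_max, and with k_off = 0 it never decreases,
        # even after the water concentration drops to zero
        params = TKParameters(k_u=k_u, k_e=k_e, k_on=k_on, B_max=b_max)
        sc = ExposureScenario.uptake_elimination(c_w, 2.0, 3.0)
        times = np.linspace(0.05, 5.0, 40)
        traj = simulate(
            params, sc, times, initial_state=(0.0, c_mp0_frac * b_max)
        )
        assert np.all(traj.c_mp <= b_max * (1 + 1e-9))
        # non-decreasing up to solver noise (rtol 1e-8 on values ~ B_max)
        assert np.all(np.diff(traj.c_mp) >= -1e-6 * max(b_max, 1.0))

    def test_fast_binding_is_uptake_limited(self, ref_params):
        # once binding is much faster than uptake, making it faster still
        # barely changes the time to half-saturation of the receptor pool:
        # the uptake rate k_u is the bottleneck
        sc = ExposureScenario.constant(0.02, 60.0)
        times = np.geomspace(0.01, 60.0, 1500)

        def t_half(k_on):
            traj = simulate(ref_params.replace(k_on=k_on), sc, times)
            return times[np.searchsorted(traj.c_mp, ref_params.B_max / 2)]

        halves = [t_half(k) for k in (2.0, 200.0, 2000.0, 2e4, 2e5)]
        assert halves == sorted(halves, reverse=True)
        # successive decades of k_on change t_half less and less ...
        assert halves[1] - halves[2] < (halves[0] - halves[1]) / 5
        # ... until it is insensitive to k_on entirely (uptake-limited)
        assert (halves[3] - halves[4]) / halves[3] < 0.02
        # in that limit, halving the uptake rate doubles the half-time
        traj = simulate(
            ref_params.replace(k_u=ref_params.k_u / 2, k_on=2000.0), sc, times
        )
        t_half_slow_uptake = times[np.searchsorted(traj.c_mp, ref_params.B_max / 2)]
        assert t_half_slow_uptake == pytest.approx(2 * halves[2], rel=0.1)


class TestSteadyState:
    def test_reference_parameters(self, ref_params):
        c_s, c_mp = steady_state(ref_params, 0.2)
        assert c_s == pytest.approx(0.4077, abs=1e-4)
        assert c_mp == 25.0

    def test_unit_rate_ratio(self):
        params = TKParameters(k_u=3.3, k_e=3.3, k_on=1.0, B_max=5.0)
        c_s, _ = steady_state(params, 7.7)
        assert c_s == pytest.approx(7.7)

    def test_long_simulation_converges_to_steady_state(self, ref_params):
        # at 0.5 µg/L (0.002 µM) receptor filling takes ~weeks; run long
        c_w = 0.002
        sc = ExposureScenario.constant(c_w, 3000.0)
        traj = simulate(ref_params, sc, [3000.0])
        c_s_ss, c_mp_ss = steady_state(ref_params, c_w)
        assert traj.c_structure[-1] == pytest.approx(c_s_ss, rel=1e-5)
        assert traj.c_mp[-1] == pytest.approx(c_mp_ss, rel=1e-4)

    def test_rejects_zero_water_and_reversible(self, ref_params):
        with pytest.raises(ValueError):
            steady_state(ref_params, 0.0)
        with pytest.warns(UserWarning):
            reversible = TKParameters(k_u=10, k_e=5, k_on=200, B_max=25, k_off=0.1)
        with pytest.raises(ValueError):
            steady_state(reversible, 0.2)
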