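"""Forcing-signal operations: printed-formula examples and ODE oracles."""

import numpy as np
import pytest

from glucotwin import (
    BolusEvent,
    ExerciseEvent,
    MealEvent,
    SimulationParams,
    glucose_rhs,
    insulin_action,
    insulin_sensitivity_trace,
    meal_rate_of_appearance,
    metabolic_rate,
    physical_activity_effect,
    renal_excretion,
)

from .oracles import rel_err, rk4_chain

GRID = np.arange(0.0, 1441.0, 1.0)


class TestMealChain:
    def test_zero_carbs_gives_zero_signal(self):
        ra = meal_rate_of_appearance(MealEvent(t_report=100, carbs=0.0), 100.0, GRID)
        assert np.all(ra == 0.0)

    def test_bioavailable_fraction_is_080(self):
        """VG * integral(RA) over a long horizon recovers 80% of the carbs."""
        t = np.arange(0.0, 4000.01, 0.5)
        meal = MealEvent(t_report=0.0, carbs=60.0, MA=1.0, TD=0.0, tauD1=10.0, tauD2=40.0)
        ra = meal_rate_of_appearance(meal, 100.0, t)
        frac = 100.0 * np.trapezoid(ra, t) / (60.0 * 1000.0)
        assert abs(frac - 0.8) < 1e-6

    def test_matches_ode_oracle(self):
        meal = MealEvent(t_report=0.0, carbs=60.0, MA=1.0, TD=0.0, tauD1=10.0, tauD2=40.0)
        ra = meal_rate_of_appearance(meal, 100.0, GRID)
        mass = 0.8 * 60.0 * 1000.0 / 100.0

        def f(t, y):
            return [-y[0] / 10.0, (y[0] - y[1]) / 40.0, (y[1] - y[2]) / 40.0]

        rec = rk4_chain(f, [0.0, 0.0, 0.0], impulses=[(0.0, 0, mass / 10.0)])
        want = np.array([rec[t][2] for t in GRID])
        assert rel_err(ra, want) < 1e-4

    def test_zero_before_onset(self):
        meal = MealEvent(t_report=300.0, carbs=50.0, TD=20.0)
        ra = meal_rate_of_appearance(meal, 120.0, GRID)
        assert np.all(ra[GRID < 320.0] == 0.0)
        assert ra[GRID > 340.0].max() > 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            MealEvent(t_report=0, carbs=50.0, tauD1=-1.0)
        with pytest.raises(ValueError):
            MealEvent(t_report=0, carbs=-5.0)


class TestInsulinChain:
    def test_no_insulin_means_no_effect(self):
        si = np.full(GRID.size, 0.4)
        x = insulin_action([], 0.0, si, 67.0, 67.0, 24.0, GRID)
        assert np.all(x == 0.0)

    def test_constant_basal_reaches_si_times_rate(self):
        """Unit DC gain through the chain: X -> SI * u under constant infusion."""
        si = np.full(14401, 0.5)
        t = np.arange(0.0, 14401.0, 1.0)
        u = 24.0 / 1440.0
        x = insulin_action([], u, si, 50.0, 50.0, 20.0, t, tauI1_basal=16.0)
        assert abs(x[-1] - 0.5 * u) / (0.5 * u) < 1e-6

    @pytest.mark.parametrize("taus", [(16.0, 67.0, 67.0, 24.0), (16.0, 67.0, 24.0, 30.0)])
    def test_bolus_matches_ode_oracle(self, taus):
        """Analytic X for one bolus (incl. repeated poles) vs RK4 at dt=0.01."""
        t1, t2, t3, t4 = taus
        SI = 0.4
        si = np.full(GRID.size, SI)
        x = insulin_action([BolusEvent(t_report=100.0, dose=6.0, TI=0.0, tauI1=t1, IA=1.0)],
                           0.0, si, t2, t3, t4, GRID)

        def f(t, y):
            return [-y[0] / t1, (y[0] - y[1]) / t2, (y[1] - y[2]) / t3,
                    (SI * y[2] - y[3]) / t4]

        rec = rk4_chain(f, [0.0] * 4, impulses=[(100.0, 0, 6.0 / t1)])
        want = np.array([rec[t][3] for t in GRID])
        assert rel_err(x, want) < 1e-4

    def test_insulin_mass_conservation(self):
        """Integral of the last-stage drive of a unit bolus equals IA * dose."""
        t = np.arange(0.0, 20000.01, 0.5)
        si = np.ones(t.size)
        from glucotwin.engine import ip_signal

        ip = ip_signal(t, [dict(t_report=0.0, dose=5.0, TI=0.0, tauI1=16.0, IA=1.2)],
                       0.0, 16.0, 67.0, 55.0)[0]
        assert abs(np.trapezoid(ip, t) - 1.2 * 5.0) / 6.0 < 1e-3


class TestPhysicalActivity:
    def test_no_events_zero(self):
        assert np.all(physical_activity_effect([], GRID) == 0.0)

    def test_onset_value_and_halving(self):
        ev = ExerciseEvent(t_report=100.0, TP=0.0, tauP_long=720.0 / np.log(2.0),
                           tauP_short=50.0, P_long=0.4, P_short=-0.2)
        pa = physical_activity_effect([ev], GRID)
        assert abs(pa[100] - (0.4 - 0.2)) < 1e-12
        # at one long half-time past the short transient, long component halves
        d = 720.0
        expect = 0.4 * 0.5 + (-0.2) * np.exp(-d / 50.0)
        assert abs(pa[820] - expect) < 1e-9

    def test_two_halvings_at_24h(self):
        """0.4 gain with 12 h half-time decays to 0.1 after 24 h."""
        tau = 720.0 / np.log(2.0)
        ev = ExerciseEvent(t_report=0.0, TP=0.0, tauP_long=tau, tauP_short=30.0,
                           P_long=0.4, P_short=0.0)
        t = np.array([0.0, 1440.0])
        pa = physical_activity_effect([ev], t)
        assert abs(pa[1] - 0.1) < 1e-12

    def test_superposition(self):
        e1 = ExerciseEvent(t_report=100.0)
        e2 = ExerciseEvent(t_report=300.0)
        both = physical_activity_effect([e1, e2], GRID)
        sep = physical_activity_effect([e1], GRID) + physical_activity_effect([e2], GRID)
        assert np.abs(both - sep).max() < 1e-12

    def test_ordering_constraint(self):
        with pytest.raises(ValueError):
            ExerciseEvent(t_report=0.0, tauP_long=30.0, tauP_short=60.0)


class TestMetabolicRate:
    def test_resting_heart_rate_gives_zero(self):
        hr_t = np.arange(0.0, 1440.0, 5.0)
        e = metabolic_rate(hr_t, np.full(hr_t.size, 65.0), 65.0, 30.0, GRID)
        assert np.all(e == 0.0)

    def test_below_resting_clipped(self):
        hr_t = np.arange(0.0, 1440.0, 5.0)
        e = metabolic_rate(hr_t, np.full(hr_t.size, 45.0), 65.0, 30.0, GRID)
        assert np.all(e == 0.0)

    def test_step_response_closed_form(self):
        """+50 bpm step: E = 50 (1 - e^(-t/tau) - (t/tau) e^(-t/tau))."""
        tau = 30.0
        hr_t = np.arange(0.0, 1441.0, 1.0)
        e = metabolic_rate(hr_t, np.full(hr_t.size, 115.0), 65.0, tau, GRID)
        want = 50.0 * (1.0 - np.exp(-GRID / tau) - (GRID / tau) * np.exp(-GRID / tau))
        assert rel_err(e, want) < 1e-9

    def test_hr_chain_matches_ode_oracle(self):
        tau = 30.0
        hr_t = np.arange(0.0, 1441.0, 1.0)
        e = metabolic_rate(hr_t, np.full(hr_t.size, 115.0), 65.0, tau, GRID)

        def f(t, y):
            return [(50.0 - y[0]) / tau, (y[0] - y[1]) / tau]

        rec = rk4_chain(f, [0.0, 0.0])
        want = np.array([rec[t][1] for t in GRID])
        assert rel_err(e, want) < 1e-4

    def test_invalid_resting_rate(self):
        with pytest.raises(ValueError):
            metabolic_rate([0.0], [70.0], -1.0, 30.0, GRID)


class TestInsulinSensitivity:
    def test_flat_when_amplitude_zero(self):
        si = insulin_sensitivity_trace(0.4, 0.0, 0.3, np.zeros(GRID.size), GRID)
        assert np.allclose(si, 0.4)

    def test_amplitude_attained(self):
        si = insulin_sensitivity_trace(1.0, 0.3, 0.1, np.zeros(GRID.size), GRID)
        assert abs(np.abs(si - 1.0).max() - 0.3) < 1e-5

    def test_quarter_day_phase_shift_moves_peak_six_hours(self):
        pa = np.zeros(GRID.size)
        si1 = insulin_sensitivity_trace(1.0, 0.4, 0.1, pa, GRID)
        si2 = insulin_sensitivity_trace(1.0, 0.4, 0.35, pa, GRID)
        t1 = GRID[np.argmax(si1[:1440])]
        t2 = GRID[np.argmax(si2[:1440])]
        assert abs(((t1 - t2) % 1440.0) - 360.0) <= 1.0

    def test_exact_24h_periodicity(self):
        t = np.arange(0.0, 2881.0, 1.0)
        si = insulin_sensitivity_trace(1.0, 0.25, 0.7, np.zeros(t.size), t)
        assert np.abs(si[:1441] - si[1440:2881]).max() < 1e-12

    def test_amplitude_bound_enforced(self):
        with pytest.raises(ValueError):
            insulin_sensitivity_trace(1.0, 0.6, 0.0, np.zeros(3), GRID[:3])


class TestRenalExcretion:
    @pytest.mark.parametrize("g,expected", [(100.0, 0.0), (162.0, 0.0), (262.0, 0.3)])
    def test_printed_values(self, g, expected):
        assert abs(renal_excretion(g) - expected) < 1e-12

    def test_piecewise_linear_slope(self):
        g = np.linspace(50.0, 500.0, 4501)
        fr = renal_excretion(g)
        slope = np.diff(fr) / np.diff(g)
        assert np.all(fr >= 0.0)
        assert np.allclose(slope[g[:-1] < 161.8], 0.0)
        assert np.allclose(slope[g[:-1] > 162.2], 0.003)


class TestGlucoseRHS:
    def test_steady_state(self):
        p = SimulationParams(EGP=0.25, GEZI=2.5e-3)
        dg, dsg = glucose_rhs(100.0, 100.0, p)
        assert abs(dg) < 1e-12 and abs(dsg) < 1e-12

    def test_h_zero_recovers_plain_insulin_action(self):
        p = SimulationParams(H=0.0, Gth=70.0, EGP=0.0, GEZI=0.0)
        dg, _ = glucose_rhs(60.0, 60.0, p, X=0.01)
        assert abs(dg - (-0.01 * 60.0)) < 1e-12

    def test_hypoglycemia_amplifies_insulin(self):
        p = SimulationParams(H=0.5, Gth=70.0, EGP=0.0, GEZI=0.0)
        below, _ = glucose_rhs(60.0, 60.0, p, X=0.01)
        above, _ = glucose_rhs(60.0, 60.0,
                               SimulationParams(H=0.0, Gth=70.0, EGP=0.0, GEZI=0.0), X=0.01)
        assert abs(below / above - 1.5) < 1e-12
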