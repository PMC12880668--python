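"""Whole-window simulation: fixed points, backend agreement, IO."""

import numpy as np
import pytest

from glucotwin import (
    BolusEvent,
    EventSet,
    ExerciseEvent,
    MealEvent,
    ModelState,
    SimulationParams,
    TraceBundle,
    simulate_sample,
)
from glucotwin.engine import IntegrationError


def busy_day():
    s0 = ModelState(G=140.0, SG=138.0, S1=0.01, S2=0.01, Ip=0.02, X=0.006)
    params = SimulationParams(SIA=0.3, SIphi=0.2, day_frac0=0.25, state0=s0, SE=0.01)
    events = EventSet(
        meals=[MealEvent(120.0, 60.0, TD=10.0, tauD1=8.0, tauD2=45.0, MA=1.1),
               MealEvent(480.0, 80.0, TD=20.0, tauD1=6.0, tauD2=60.0, MA=0.9)],
        boluses=[BolusEvent(115.0, 6.0, TI=5.0, tauI1=18.0, IA=1.0),
                 BolusEvent(475.0, 8.0, TI=0.0, tauI1=14.0, IA=1.1)],
        exercises=[ExerciseEvent(700.0, TP=10.0, tauP_long=900.0, tauP_short=50.0,
                                 P_long=0.5, P_short=-0.2)],
        basal_rate=24.0 / 1440.0, tauI1_basal=16.0)
    hr_t = np.arange(0.0, 1441.0, 5.0)
    hr = np.full(hr_t.size, 65.0)
    hr[(hr_t > 700.0) & (hr_t < 760.0)] += 60.0
    return params, events, hr_t, hr


def test_zero_input_fixed_point():
    """G0 = EGP/GEZI with no inputs stays constant over 24 h."""
    p = SimulationParams(EGP=0.25, GEZI=2.5e-3, SIA=0.0,
                         state0=ModelState(G=100.0, SG=100.0))
    tb = simulate_sample(p)
    assert np.abs(tb.G - 100.0).max() < 0.1
    assert np.abs(tb.SG - 100.0).max() < 0.1


def test_no_insulin_glucose_rises_toward_renal_balance():
    p = SimulationParams(EGP=1.6, GEZI=2.0e-3, SIA=0.0,
                         state0=ModelState(G=150.0, SG=150.0))
    tb = simulate_sample(p)
    assert np.all(np.diff(tb.G[:600]) > 0.0)
    assert tb.G[-1] > 300.0


def test_backends_agree_on_busy_day():
    params, events, hr_t, hr = busy_day()
    a = simulate_sample(params, events, hr_t, hr, backend="analytic_forcing")
    b = simulate_sample(params, events, hr_t, hr, backend="full_ode", dt_sub=0.1)
    assert np.abs(a.SG - b.SG).max() < 0.5
    assert np.abs(a.G - b.G).max() < 0.5


def test_positivity_and_bundle_invariants():
    params, events, hr_t, hr = busy_day()
    tb = simulate_sample(params, events, hr_t, hr)
    assert np.all(tb.G > 0) and np.all(tb.SG > 0)
    assert np.all(tb.RA >= 0) and np.all(tb.FR >= 0) and np.all(tb.E >= 0)
    assert np.all(tb.X >= 0)
    for sig in (tb.SG, tb.G, tb.X, tb.RA, tb.PA, tb.SI, tb.E, tb.FR):
        assert sig.shape == tb.t_grid.shape


def test_integration_error_carries_time():
    # a constant metabolic drain with no production drives G through zero
    p = SimulationParams(EGP=0.0, GEZI=1e-3, SIA=0.0, SE=0.05, tauE=10.0,
                         state0=ModelState(G=50.0, SG=50.0))
    hr_t = np.arange(0.0, 1441.0, 5.0)
    hr = np.full(hr_t.size, 150.0)
    with pytest.raises(IntegrationError) as ei:
        simulate_sample(p, EventSet(), hr_t, hr)
    assert ei.value.t is not None and 0.0 < ei.value.t <= 1440.0


def test_trace_csv_round_trip(tmp_path):
    params, events, hr_t, hr = busy_day()
    tb = simulate_sample(params, events, hr_t, hr)
    path = tmp_path / "trace.csv"
    tb.to_csv(path)
    back = TraceBundle.from_csv(path)
    for name in ("t_grid", "SG", "G", "X", "RA", "PA", "SI", "E", "FR"):
        assert np.allclose(getattr(tb, name), getattr(back, name))


def test_initial_meal_chain_contents_rejected():
    p = SimulationParams(state0=ModelState(G=120.0, SG=120.0, D1=1.0))
    with pytest.raises(ValueError):
        simulate_sample(p)
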