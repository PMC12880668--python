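"""Single-sample forcing-signal operations on a time grid.

These are the user-facing counterparts of the batched engine primitives:
they take event dataclasses and scalar parameters and return 1-D signals.
"""

from __future__ import annotations

import numpy as np

from . import engine
from .events import BolusEvent, ExerciseEvent, MealEvent
from .params import SimulationParams

__all__ = [
    "meal_rate_of_appearance",
    "insulin_action",
    "physical_activity_effect",
    "metabolic_rate",
    "insulin_sensitivity_trace",
    "renal_excretion",
    "glucose_rhs",
]


def _meal_dict(m: MealEvent) -> dict:
    return dict(t_report=m.t_report, carbs=m.carbs, TD=m.TD, tauD1=m.tauD1, tauD2=m.tauD2, MA=m.MA)


def _bolus_dict(b: BolusEvent) -> dict:
    return dict(t_report=b.t_report, dose=b.dose, TI=b.TI, tauI1=b.tauI1, IA=b.IA)


def _exercise_dict(e: ExerciseEvent) -> dict:
    return dict(t_report=e.t_report, TP=e.TP, tauP_long=e.tauP_long, tauP_short=e.tauP_short,
                P_long=e.P_long, P_short=e.P_short)


def meal_rate_of_appearance(meal: MealEvent, VG: float, t_grid: np.ndarray) -> np.ndarray:
    """Rate of glucose appearance (mg/dL/min) of one meal on t_grid.

    Three cascaded first-order stages (tauD1, tauD2, tauD2) driven by an
    impulse of glucose mass 0.8 * MA * carbs * 1000 mg, scaled by 1/VG.
    """
    return engine.ra_signal(np.asarray(t_grid, dtype=float), [_meal_dict(meal)], VG)[0]


def insulin_action(
    boluses: list[BolusEvent],
    basal_rate: float,
    SI_trace: np.ndarray,
    tauI2: float,
    tauI3: float,
    tauI4: float,
    t_grid: np.ndarray,
    tauI1_basal: float = 16.0,
    S1_0: float = 0.0,
    S2_0: float = 0.0,
    Ip_0: float = 0.0,
    X0: float = 0.0,
) -> np.ndarray:
    """Insulin effect X (1/min) on t_grid.

    Boluses are impulses of mass IA*dose into their own first stage; basal is
    a constant infusion (U/min) for the whole window; the final stage is
    driven by SI(t) * Ip(t).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    dt = float(t_grid[1] - t_grid[0])
    ip = engine.ip_signal(t_grid, [_bolus_dict(b) for b in boluses], basal_rate,
                          tauI1_basal, tauI2, tauI3, S1_0=S1_0, S2_0=S2_0, Ip_0=Ip_0)
    si = np.broadcast_to(np.asarray(SI_trace, dtype=float), ip.shape)
    return engine.x_signal(si, ip, dt, tauI4, X0=X0)[0]


def physical_activity_effect(events: list[ExerciseEvent], t_grid: np.ndarray) -> np.ndarray:
    """Summed exponential short/long insulin-sensitivity perturbations."""
    return engine.pa_signal(np.asarray(t_grid, dtype=float), [_exercise_dict(e) for e in events])[0]


def metabolic_rate(hr_t, hr_bpm, hr_rest: float, tauE: float, t_grid: np.ndarray) -> np.ndarray:
    """Metabolic rate E (bpm excess) from a heart-rate stream on t_grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    dt = float(t_grid[1] - t_grid[0])
    hr = engine.hr_to_grid(hr_t, hr_bpm, t_grid, hr_rest)
    return engine.e_signal(hr, dt, tauE, hr_rest)[0]


def insulin_sensitivity_trace(SIE: float, SIA: float, SIphi: float, pa: np.ndarray,
                              t_grid: np.ndarray, day_frac0: float = 0.0) -> np.ndarray:
    """SI(t) = SIE (1+PA(t)) (1 + SIA sin(2 pi (t_day + SIphi))), period 24 h."""
    if SIA > SimulationParams.SIA_MAX:
        raise ValueError(f"SIA exceeds its bound {SimulationParams.SIA_MAX}")
    return engine.si_signal(np.asarray(t_grid, dtype=float), SIE, SIA, SIphi,
                            np.atleast_2d(pa), day_frac0)[0]


def renal_excretion(G):
    """FR = 0.003 (G - 162) mg/dL/min above 162 mg/dL, else 0; continuous."""
    return engine.renal_excretion(G)


def glucose_rhs(G: float, SG: float, p: SimulationParams, X: float = 0.0, E: float = 0.0,
                RA: float = 0.0) -> tuple[float, float]:
    """(dG/dt, dSG/dt) at one instant with all inputs evaluated there."""
    dG = float(engine.glucose_rhs_arrays(np.asarray(G, dtype=float), X, E, RA,
                                         p.EGP, p.GEZI, p.SE, p.H, p.Gth))
    dSG = (G - SG) / p.tauG
    return dG, dSG
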