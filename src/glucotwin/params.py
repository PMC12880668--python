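"""Physiological state and parameter bundles for one 24 h simulation.

Internal units throughout: minutes, mg/dL, grams (scaled to mg where mass is
conserved), insulin doses in units (U).  Insulin sensitivity SI carries the
microU-to-U conversion in its effective gain, so X = SI * Ip has units 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ModelState", "SimulationParams", "BIOAVAILABILITY", "RENAL_THRESHOLD", "RENAL_SLOPE"]

#: fixed fraction of reported carbohydrate reaching plasma
BIOAVAILABILITY = 0.8
#: renal excretion threshold (mg/dL) and slope (1/min), Hovorka-type term
RENAL_THRESHOLD = 162.0
RENAL_SLOPE = 0.003


@dataclass
class ModelState:
    """Compartment values at one instant."""

    G: float = 120.0    # blood glucose (mg/dL)
    SG: float = 120.0   # subcutaneous glucose (mg/dL)
    S1: float = 0.0     # insulin chain stage 1 (U/min)
    S2: float = 0.0     # insulin chain stage 2 (U/min)
    Ip: float = 0.0     # plasma-acting insulin rate (U/min)
    X: float = 0.0      # insulin effect (1/min)
    D1: float = 0.0     # meal chain stage 1 (mg/dL/min)
    D2: float = 0.0     # meal chain stage 2 (mg/dL/min)
    RA: float = 0.0     # rate of glucose appearance (mg/dL/min)
    E1: float = 0.0     # metabolic-rate stage 1 (bpm excess)
    E: float = 0.0      # metabolic rate (bpm excess)

    def __post_init__(self) -> None:
        if self.G <= 0 or self.SG <= 0:
            raise ValueError("glucose state must be positive")


@dataclass
class SimulationParams:
    """Everything needed to simulate one 24 h window (besides the events)."""

    VG: float = 120.0        # glucose distribution volume (dL)
    GEZI: float = 2.5e-3     # glucose effectiveness at zero insulin (1/min)
    EGP: float = 1.5         # endogenous glucose production (mg/dL/min)
    SIE: float = 0.4         # mean insulin sensitivity (1/U, see module docstring)
    SIA: float = 0.2         # intraday SI sinusoid amplitude, in [0, 0.5]
    SIphi: float = 0.0       # intraday SI phase (fraction of a day)
    tauG: float = 15.0       # subcutaneous glucose lag (min)
    tauI2: float = 60.0      # insulin chain stage 2 (min)
    tauI3: float = 60.0      # insulin chain stage 3 (min)
    tauI4: float = 25.0      # insulin effect stage (min)
    tauE: float = 30.0       # metabolic-rate stage constant (min)
    SE: float = 0.01         # metabolic-rate gain (mg/dL/min per bpm excess)
    H: float = 0.0           # hypoglycemia amplification of insulin action
    Gth: float = 65.0        # hypoglycemia threshold (mg/dL)
    sigma: float = 10.0      # CGM noise standard deviation (mg/dL)
    hr_rest: float = 65.0    # resting heart rate (bpm)
    day_frac0: float = 0.0   # time of day of the window start (fraction of a day)
    state0: ModelState = field(default_factory=ModelState)

    SIA_MAX = 0.5

    def __post_init__(self) -> None:
        for name in ("tauG", "tauI2", "tauI3", "tauI4", "tauE"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.VG <= 0:
            raise ValueError("VG must be positive")
        if not 0.0 <= self.SIA <= self.SIA_MAX:
            raise ValueError(f"SIA must lie in [0, {self.SIA_MAX}]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.H < 0:
            raise ValueError("H must be non-negative")
        if self.hr_rest <= 0:
            raise ValueError("hr_rest must be positive")
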