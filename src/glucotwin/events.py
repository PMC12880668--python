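"""Timed input events for a 24 h sample and their event-level modifiers.

Times are minutes from the window start.  Each event carries both the
observed report (time, grams, units) and the latent modifiers attached to it
(start offset, absorption time constants, report-uncertainty coefficient);
the modifiers default to the deterministic values used when simulating
without uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["MealEvent", "BolusEvent", "ExerciseEvent", "EventSet"]


@dataclass
class MealEvent:
    t_report: float                 # min from window start
    carbs: float                    # g
    fat: float = 0.0                # g
    protein: float = 0.0            # g
    TD: float = 0.0                 # start offset (min)
    tauD1: float = 6.0              # first absorption stage (min)
    tauD2: float = 55.0             # second/third absorption stage (min)
    MA: float = 1.0                 # carb-report coefficient

    def __post_init__(self) -> None:
        if self.carbs < 0:
            raise ValueError("carbs must be non-negative")
        if self.tauD1 <= 0 or self.tauD2 <= 0:
            raise ValueError("meal time constants must be positive")
        if self.MA <= 0:
            raise ValueError("MA must be positive")


@dataclass
class BolusEvent:
    t_report: float                 # min from window start
    dose: float                     # insulin units
    TI: float = 0.0                 # start offset (min)
    tauI1: float = 16.0             # first insulin stage (min)
    IA: float = 1.0                 # bolus-report coefficient

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.tauI1 <= 0:
            raise ValueError("tauI1 must be positive")
        if self.IA <= 0:
            raise ValueError("IA must be positive")


@dataclass
class ExerciseEvent:
    t_report: float                 # min from window start
    TP: float = 0.0                 # start offset (min)
    tauP_long: float = 1040.0       # long-effect decay (min)
    tauP_short: float = 60.0        # short-effect decay (min)
    P_long: float = 0.4             # long-effect gain (>= 0)
    P_short: float = 0.0            # short-effect gain (signed)

    def __post_init__(self) -> None:
        if not self.tauP_long > self.tauP_short > 0:
            raise ValueError("require tauP_long > tauP_short > 0")
        if self.P_long < 0:
            raise ValueError("P_long must be non-negative")


@dataclass
class EventSet:
    meals: list[MealEvent] = field(default_factory=list)
    boluses: list[BolusEvent] = field(default_factory=list)
    exercises: list[ExerciseEvent] = field(default_factory=list)
    basal_rate: float = 0.0         # constant infusion into S1 (U/min)
    tauI1_basal: float = 16.0       # first-stage constant for the basal path

    def copy(self) -> "EventSet":
        return EventSet(
            meals=[replace(m) for m in self.meals],
            boluses=[replace(b) for b in self.boluses],
            exercises=[replace(e) for e in self.exercises],
            basal_rate=self.basal_rate,
            tauI1_basal=self.tauI1_basal,
        )
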