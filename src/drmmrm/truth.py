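"""True drug-effect model used to generate data.

The drug effect on log-scale change from baseline in UACR follows an
Emax model in dose, scaled by a time-course multiplier in [0, 1]:

    effect(dose, t) = Emax(ED50) * f_tc(t) * dose / (ED50 + dose)

Emax is anchored so that the 100 mg dose produces exactly a 40%
reduction (log 0.6) at full effect, whatever the ED50:

    Emax(ED50) = log(0.6) * (100 + ED50) / 100

Time-courses: "direct" (full effect from the first visit),
"exponential" (1 - 2^(-t/1.75), half-life 1.75 weeks) and "linear"
(t/16, full effect at the week-16 end-of-study visit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TruthParams",
    "emax_for_ed50",
    "timecourse_multiplier",
    "true_effect",
    "TARGET_REDUCTION",
    "MAX_EFFECT_LOG",
]

#: Multiplier on UACR at the top dose, full effect: a 40% reduction.
TARGET_REDUCTION = 0.6
#: log-scale effect of the top dose at full effect: log(0.6).
MAX_EFFECT_LOG = math.log(TARGET_REDUCTION)

_TOP_DOSE = 100.0
_EXP_HALF_LIFE = 1.75
_LINEAR_RAMP_END = 16.0


@dataclass(frozen=True)
class TruthParams:
    """Parameters of the generative dose-response model."""

    ed50: float
    timecourse: str
    half_life_weeks: float = _EXP_HALF_LIFE
    ramp_end_weeks: float = _LINEAR_RAMP_END
    target_reduction: float = TARGET_REDUCTION

    def __post_init__(self) -> None:
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")
        if self.half_life_weeks <= 0 or self.ramp_end_weeks <= 0:
            raise ValueError("time-course constants must be positive")


def emax_for_ed50(ed50: float) -> float:
    """Maximal log-scale effect for a given ED50.

    Chosen so the 100 mg dose attains exactly ``log(0.6)`` at full
    effect: ``Emax = log(0.6) * (100 + ed50) / 100``.
    """
    if not ed50 > 0:
        raise ValueError("ed50 must be positive")
    return MAX_EFFECT_LOG * (_TOP_DOSE + ed50) / _TOP_DOSE


def timecourse_multiplier(
    timecourse: str,
    t: float,
    half_life_weeks: float = _EXP_HALF_LIFE,
    ramp_end_weeks: float = _LINEAR_RAMP_END,
) -> float:
    """Fraction of the full effect attained ``t`` weeks after start.

    direct -> 1; exponential -> 1 - exp(-log(2)/half_life * t);
    linear -> t / ramp_end, capped at 1 beyond the ramp end.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if timecourse == "direct":
        return 1.0
    if timecourse == "exponential":
        return 1.0 - math.exp(-math.log(2.0) / half_life_weeks * t)
    if timecourse == "linear":
        return min(t / ramp_end_weeks, 1.0)
    raise ValueError(f"unknown timecourse {timecourse!r}")


def true_effect(params: TruthParams, dose: float, t: float) -> float:
    """True log-scale drug effect at ``dose`` mg, ``t`` weeks.

    Zero for placebo (dose 0); magnitude non-decreasing in dose and t.
    """
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    if dose == 0:
        return 0.0
    emax = emax_for_ed50(params.ed50)
    frac = timecourse_multiplier(
        params.timecourse, t, params.half_life_weeks, params.ramp_end_weeks
    )
    return emax * frac * dose / (params.ed50 + dose)
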