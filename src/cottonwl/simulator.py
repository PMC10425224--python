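"""Minimal daily-step forward simulator of waterlogging stress on growth.

A proof-of-concept coupling of the fitted stress-response curves to a
potential-growth accumulator: each day the potential biomass increment is
multiplied by the photosynthesis stress factor evaluated at the elapsed
waterlogging duration (clamped to [0, 1]). This is the carbon-supply route
into a crop model — organ partitioning is left untouched because the
relative organ responses were observed to be similar. Post-release recovery
of the plant (as opposed to the soil) is not quantified by the source
experiments, so the default holds the end-of-treatment factor; an optional
linear relaxation back to 1 is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import CurveRegistry, evaluate_curve, load_registry
from .errors import DomainError
from .oxygen import OxygenModelParams, anoxic_days

#: Parameter whose response curve drives the stress factor by default.
DEFAULT_STRESS_PARAMETER = "P"


@dataclass(frozen=True)
class Schedule:
    """Waterlogging schedule on a days-after-sowing axis."""

    duration: float  # days of waterlogging
    onset: float = 15.0  # day after sowing when ponding starts
    horizon: float = 30.0  # simulation length, days after sowing

    def __post_init__(self) -> None:
        if self.onset < 1:
            raise DomainError("onset must be >= 1 day after sowing")
        if self.duration < 0:
            raise DomainError("duration must be non-negative")
        if self.onset + self.duration > self.horizon:
            raise DomainError("schedule exceeds horizon (onset + duration > horizon)")

    def elapsed(self, day: float) -> float:
        """Elapsed waterlogging days at a given day after sowing."""
        return float(np.clip(day - self.onset, 0.0, self.duration))


@dataclass
class SimulationResult:
    """Daily stress factors and biomass for one schedule."""

    daily: pd.DataFrame  # day, elapsed, stress_factor, biomass
    relative_biomass: float
    schedule: Schedule


def _stress_factor(
    schedule: Schedule,
    day: float,
    curve,
    recovery_days: float,
    elapsed_override: float | None = None,
) -> float:
    release = schedule.onset + schedule.duration
    e = schedule.elapsed(day) if elapsed_override is None else elapsed_override
    f = evaluate_curve(curve, e, mode="clamp01")
    if recovery_days > 0 and day >= release and schedule.duration > 0:
        f_end = evaluate_curve(curve, schedule.duration, mode="clamp01")
        frac = min(1.0, (day - release) / recovery_days)
        f = f_end + (1.0 - f_end) * frac
    return f


def stress_trajectory(
    schedule: Schedule,
    registry: CurveRegistry | None = None,
    parameter_code: str = DEFAULT_STRESS_PARAMETER,
    recovery_days: float = 0.0,
) -> pd.DataFrame:
    """Daily (day, elapsed, factor) table for one parameter's stress factor."""
    registry = registry if registry is not None else load_registry()
    curve = registry[parameter_code]
    days = np.arange(0.0, schedule.horizon + 1.0)
    rows = [
        {
            "day": d,
            "elapsed": schedule.elapsed(d),
            "factor": _stress_factor(schedule, d, curve, recovery_days),
        }
        for d in days
    ]
    return pd.DataFrame(rows)


def simulate_growth(
    schedule: Schedule,
    registry: CurveRegistry | None = None,
    daily_potential_increment: float = 1.0,
    recovery_days: float = 0.0,
    parameter_code: str = DEFAULT_STRESS_PARAMETER,
    use_anoxic_days: bool = False,
    oxygen_params: OxygenModelParams | None = None,
) -> SimulationResult:
    """Accumulate stress-modified potential growth over the horizon.

    Each day's increment is scaled by the stress factor from the chosen
    response curve at the elapsed waterlogging duration (or, with
    ``use_anoxic_days``, at the running anoxic-day count from the oxygen
    model). ``relative_biomass`` is the stressed accumulator divided by the
    unstressed control at the horizon.
    """
    registry = registry if registry is not None else load_registry()
    curve = registry[parameter_code]
    if daily_potential_increment <= 0:
        raise DomainError("daily_potential_increment must be positive")

    days = np.arange(0.0, schedule.horizon + 1.0)
    biomass = 0.0
    rows = []
    for d in days:
        if use_anoxic_days:
            params = oxygen_params if oxygen_params is not None else OxygenModelParams()
            e = float(anoxic_days(schedule.elapsed(d), params))
            f = _stress_factor(schedule, d, curve, recovery_days, elapsed_override=e)
        else:
            f = _stress_factor(schedule, d, curve, recovery_days)
        biomass += daily_potential_increment * f
        rows.append(
            {
                "day": d,
                "elapsed": schedule.elapsed(d),
                "stress_factor": f,
                "biomass": biomass,
            }
        )

    control_biomass = daily_potential_increment * days.size
    daily = pd.DataFrame(rows)
    return SimulationResult(
        daily=daily,
        relative_biomass=biomass / control_biomass,
        schedule=schedule,
    )
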