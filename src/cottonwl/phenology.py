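"""Delay of the first square (flower bud) as a function of waterlogging.

The first square is the earliest reproductive milestone in cotton. In the
emulated experiment the control and 2-day treatments squared 25 days after
emergence, 4 and 6 days of waterlogging delayed squaring by 2 and 4 days,
and the 8-14 day treatments had not squared when observation ended at 30
days — those observations are censored and excluded from fitting rather
than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curves import ResponseFamily
from .errors import CensoredResult, RankError
from .fitting import DurationResponseResults, fit_family

#: Observation window (days from emergence) beyond which squaring is censored.
OBSERVATION_WINDOW = 30


@dataclass(frozen=True)
class SquaringObservation:
    """Days from emergence to the first square for one treatment."""

    duration: float  # days of waterlogging
    days_to_square: float | None = None  # None when censored
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and (self.days_to_square is None or self.days_to_square <= 0):
            raise ValueError("uncensored observations need days_to_square > 0")


def default_observations() -> list[SquaringObservation]:
    """The packaged squaring observations for the 8-treatment design."""
    return [
        SquaringObservation(0, 25),
        SquaringObservation(2, 25),
        SquaringObservation(4, 27),
        SquaringObservation(6, 29),
        SquaringObservation(8, censored=True),
        SquaringObservation(10, censored=True),
        SquaringObservation(12, censored=True),
        SquaringObservation(14, censored=True),
    ]


def read_observations(path) -> list[SquaringObservation]:
    """Read observations from delimited text: duration, days_to_square, censored."""
    df = pd.read_csv(path, comment="#")
    obs = []
    for row in df.itertuples():
        censored = bool(getattr(row, "censored", False))
        dts = None if censored else float(row.days_to_square)
        obs.append(SquaringObservation(float(row.duration), dts, censored))
    return obs


def fit_square_timing(
    observations: Iterable[SquaringObservation] | None = None,
    family: ResponseFamily | str = ResponseFamily.QUADRATIC,
) -> DurationResponseResults:
    """Least-squares fit of days-to-square against waterlogging duration.

    Censored treatments are excluded; needs at least arity + 1 uncensored
    observations.
    """
    if observations is None:
        observations = default_observations()
    family = ResponseFamily(family)
    points = [(o.duration, o.days_to_square) for o in observations if not o.censored]
    if len(points) < family.arity + 1:
        raise RankError(
            f"need >= {family.arity + 1} uncensored observations, got {len(points)}"
        )
    return fit_family(points, family, parameter_code="SQUARE",
                      description="days from emergence to first square")


def predict_square_day(
    fit: DurationResponseResults, duration: float
) -> tuple[float, int]:
    """Predicted days to first square at a waterlogging duration.

    Returns the real-valued prediction and its half-away-from-zero rounding.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    value = float(fit.predict(np.asarray(duration, dtype=float)))
    rounded = int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))
    return value, rounded


def square_delay(
    observations: Iterable[SquaringObservation] | None = None, duration: float = 0.0
) -> float:
    """Observed squaring delay of a treatment relative to the 0-day control."""
    if observations is None:
        observations = default_observations()
    by_duration = {o.duration: o for o in observations}
    for d in (0.0, float(duration)):
        if d not in by_duration:
            raise KeyError(f"no observation at duration {d}")
        if by_duration[d].censored:
            raise CensoredResult(
                f"treatment at {d} days did not square within the "
                f"{OBSERVATION_WINDOW}-day window"
            )
    return by_duration[float(duration)].days_to_square - by_duration[0.0].days_to_square
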