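"""Synthetic replicate-level data with the structure of the pot experiment.

The emulated design is eight waterlogging treatments (0, 2, ..., 14 days of
ponding) with five replicate pots each, and 26 measured parameters per pot.
Treatment-cell means are driven by the packaged response curves scaled by a
control-level value in native units; replicate scatter is Gaussian with a
constant coefficient of variation, floored at zero. Replicate dispersion is
a convention (the source experiment reports none), so recovery tests
exercise the pipeline, not real biological variance; see the methods note.

Only the control mainstem leaf number (9.4) is a published value; every
other control mean is a synthetic placeholder of plausible magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import CurveRegistry, evaluate_curve, evaluate_trajectory, load_registry
from .wsri import TABLE_COLUMNS, TreatmentTable

DESIGN_DURATIONS = (0, 2, 4, 6, 8, 10, 12, 14)
DESIGN_REPS = 5

#: Control-treatment means in native units. LN is the published control
#: mainstem leaf count; all other entries are synthetic placeholders chosen
#: for plausible magnitude only.
_PLACEHOLDER_CONTROL_MEANS: dict[str, float] = {
    "PH": 35.0,      # plant height, cm
    "SD": 5.0,       # stem diameter, mm
    "LN": 9.4,       # mainstem leaves (published control value)
    "LA": 350.0,     # leaf area, cm^2
    "DWL": 2.5,      # leaf dry weight, g
    "DWS": 1.8,      # stem dry weight, g
    "DWSh": 4.3,     # shoot dry weight, g
    "DWT": 5.5,      # whole-plant dry weight, g
    "RL": 850.0,     # root length, cm
    "RSA": 120.0,    # root surface area, cm^2
    "RV": 1.5,       # root volume, cm^3
    "RWD": 1.2,      # root dry weight, g
    "RT": 1200.0,    # root tips, count
    "RC": 400.0,     # root crossings, count
    "CHL": 28.0,     # chlorophyll index, ug/cm^2
    "FL": 0.6,       # flavonoid index
    "AN": 0.12,      # anthocyanin index
    "NBI": 45.0,     # nitrogen balance index
    "P": 25.0,       # net photosynthesis, umol CO2/m^2/s
    "E": 6.0,        # transpiration, mmol H2O/m^2/s
    "Ci/Ca": 0.7,    # intercellular/ambient CO2 ratio
    "Gs": 0.5,       # stomatal conductance, mol/m^2/s
    "ETR": 120.0,    # electron transport rate, umol/m^2/s
    "phiPS2": 0.25,  # PSII quantum yield
    "NPQ": 1.5,      # nonphotochemical quenching
    "Fv'/Fm'": 0.55, # PSII effective fluorescence
}


def default_control_means() -> dict[str, float]:
    """Control means covering every packaged registry code (LN published,
    the rest synthetic placeholders)."""
    return dict(_PLACEHOLDER_CONTROL_MEANS)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic experiment."""

    durations: tuple = DESIGN_DURATIONS
    n_reps: int = DESIGN_REPS
    control_means: Mapping[str, float] = field(default_factory=default_control_means)
    cv: float = 0.05
    registry: CurveRegistry | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if any(m <= 0 for m in self.control_means.values()):
            raise ValueError("control_means must be strictly positive")

    def resolve_registry(self) -> CurveRegistry:
        return self.registry if self.registry is not None else load_registry()


def generate_dataset(config: GeneratorConfig = GeneratorConfig()) -> TreatmentTable:
    """Draw a replicate-level treatment table from the configured design.

    Cell mean = control_mean x curve(duration) floored at zero; replicates
    are independent Normal(mean, cv * mean) draws floored at zero. The table
    is a pure function of the seed.
    """
    registry = config.resolve_registry()
    for code in config.control_means:
        if code not in registry:
            raise KeyError(f"control mean given for {code!r}, absent from registry")

    rng = np.random.default_rng(config.seed)
    records = []
    for code, control in config.control_means.items():
        curve = registry[code]
        for d in sorted(config.durations):
            mu = control * evaluate_curve(curve, float(d), mode="clamp_nonneg")
            sd = config.cv * mu
            draws = mu + sd * rng.standard_normal(config.n_reps) if sd > 0 else np.full(config.n_reps, mu)
            draws = np.maximum(draws, 0.0)
            for rep, value in enumerate(draws, start=1):
                records.append((int(d), rep, code, float(value)))
    return TreatmentTable(pd.DataFrame(records, columns=TABLE_COLUMNS))


def generate_wsri_points(
    parameter_code: str,
    durations: Sequence[float] = DESIGN_DURATIONS,
    noise_sd: float = 0.0,
    seed: int = 0,
    registry: CurveRegistry | None = None,
) -> np.ndarray:
    """(duration, index) pairs straight in WSRI space, for fitting tests.

    The curve is evaluated raw (no clamping, no renormalisation) and
    additive Gaussian noise of the given standard deviation applied;
    noise_sd = 0 returns the curve values exactly.
    """
    registry = registry if registry is not None else load_registry()
    curve = registry[parameter_code]
    x = np.asarray(durations, dtype=float)
    y = evaluate_trajectory(curve, x)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(x.size)
    return np.column_stack([x, y])
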