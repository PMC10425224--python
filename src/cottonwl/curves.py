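"""Duration-response curve families and the packaged coefficient registry.

Each measured plant parameter's waterlogging stress response index (WSRI,
the treatment mean normalised by the 0-day control mean) is modelled as a
function of waterlogging duration ``x`` in days by one of three families:

- linear:     y = slope * x + intercept
- quadratic:  y = a * x**2 + b * x + c
- exp_decay:  y = a * exp(b * x)   (amplitude a > 0, rate b < 0 per day)

The packaged registry carries 26 fitted curves, one per parameter, with
coefficients exactly as published. Published linear rows are internally
inconsistent about which printed column is the slope and which the
intercept; :func:`disambiguate_linear` resolves the orientation by choosing
the candidate whose intercept is nearest 1, since a stress index is 1 by
construction at zero stress. Rows where the resolution reveals a residual
oddity carry provenance flags rather than silently edited coefficients.
"""

from __future__ import annotations

import enum
import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

REGISTRY_VERSION = "published-2023"

#: |y(0) - 1| beyond which a disambiguated linear intercept is considered
#: anomalous (only the NPQ row trips this for the packaged registry).
INTERCEPT_ANOMALY_TOL = 0.5


class ResponseFamily(str, enum.Enum):
    """The three response-function families, with fixed coefficient arity."""

    LINEAR = "linear"
    QUADRATIC = "quadratic"
    EXP_DECAY = "exp_decay"

    @property
    def arity(self) -> int:
        return _ARITY[self]


_ARITY = {
    ResponseFamily.LINEAR: 2,
    ResponseFamily.QUADRATIC: 3,
    ResponseFamily.EXP_DECAY: 2,
}

#: Provenance flags attachable to a registry entry.
FLAG_COLUMN_SWAPPED = "column_swapped"
FLAG_DIRECTION_CONFLICT = "direction_conflict"
FLAG_INTERCEPT_ANOMALY = "intercept_anomaly"


def disambiguate_linear(a_printed: float, b_printed: float) -> tuple[float, float, bool]:
    """Resolve the (slope, intercept) orientation of a printed linear row.

    Candidate A reads the printed pair as (slope=a, intercept=b); candidate B
    swaps them. The candidate whose intercept is nearest 1 wins, ties going
    to candidate A. Returns ``(slope, intercept, swapped)``.
    """
    score_a = abs(b_printed - 1.0)
    score_b = abs(a_printed - 1.0)
    if score_b < score_a:
        return b_printed, a_printed, True
    return a_printed, b_printed, False


@dataclass(frozen=True)
class ResponseCurve:
    """One parameter's fitted duration -> WSRI function.

    ``coefficients`` are in canonical orientation: linear (slope, intercept),
    quadratic (a, b, c), exp_decay (amplitude, rate).
    """

    parameter_code: str
    description: str
    family: ResponseFamily
    coefficients: tuple[float, ...]
    r_squared: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.family.arity:
            raise SchemaError(
                f"{self.parameter_code!r}: family {self.family.value} expects "
                f"{self.family.arity} coefficients, got {len(self.coefficients)}"
            )

    def __call__(self, duration, mode: str = "raw"):
        return evaluate_curve(self, duration, mode)

    def with_direction_corrected(self) -> "ResponseCurve":
        """Return a copy with the slope negated if flagged direction_conflict.

        Opt-in repair for linear rows whose printed slope sign contradicts
        the narrative trend (CHL, NBI in the packaged registry); the stored
        registry always keeps coefficients as printed.
        """
        if FLAG_DIRECTION_CONFLICT not in self.flags or self.family is not ResponseFamily.LINEAR:
            return self
        slope, intercept = self.coefficients
        return replace(self, coefficients=(-slope, intercept))


def _evaluate_raw(curve: ResponseCurve, x: np.ndarray) -> np.ndarray:
    c = curve.coefficients
    if curve.family is ResponseFamily.LINEAR:
        return c[0] * x + c[1]
    if curve.family is ResponseFamily.QUADRATIC:
        return c[0] * x**2 + c[1] * x + c[2]
    return c[0] * np.exp(c[1] * x)


def evaluate_curve(curve: ResponseCurve, duration, mode: str = "raw"):
    """Evaluate a response curve at one or more durations (days, >= 0).

    ``mode`` controls physical bounding: ``raw`` returns the fitted value,
    ``clamp_nonneg`` floors at 0, ``clamp01`` additionally caps at 1.
    """
    x = np.asarray(duration, dtype=float)
    if np.any(x < 0):
        raise DomainError("duration must be non-negative (days since onset)")
    y = _evaluate_raw(curve, x)
    if mode == "raw":
        pass
    elif mode == "clamp_nonneg":
        y = np.maximum(y, 0.0)
    elif mode == "clamp01":
        y = np.clip(y, 0.0, 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(y) if np.isscalar(duration) or np.ndim(duration) == 0 else y


def evaluate_trajectory(
    curve: ResponseCurve, durations: Sequence[float], mode: str = "raw"
) -> np.ndarray:
    """Evaluate a curve elementwise along an ordered duration grid."""
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise DomainError("durations must be non-empty")
    return np.asarray(evaluate_curve(curve, durations, mode))


def percent_change(curve: ResponseCurve, duration: float) -> float:
    """Percent decline of the index at ``duration`` relative to duration 0.

    Positive for declining parameters; negative for stress-induced increases
    (e.g. flavonoids).
    """
    y0 = evaluate_curve(curve, 0.0)
    if y0 == 0.0:
        raise DomainError(f"{curve.parameter_code!r}: value at duration 0 is zero")
    return 100.0 * (1.0 - evaluate_curve(curve, duration) / y0)


@dataclass(frozen=True)
class CurveRegistry:
    """Immutable mapping of parameter codes to fitted response curves."""

    entries: Mapping[str, ResponseCurve]
    version: str = REGISTRY_VERSION

    def __getitem__(self, code: str) -> ResponseCurve:
        try:
            return self.entries[code]
        except KeyError:
            raise KeyError(
                f"unknown parameter code {code!r}; known: {sorted(self.entries)}"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def codes(self) -> list[str]:
        return list(self.entries)

    def family_counts(self) -> dict[ResponseFamily, int]:
        counts = {f: 0 for f in ResponseFamily}
        for curve in self:
            counts[curve.family] += 1
        return counts

    def flagged(self, flag: str) -> list[str]:
        return [c.parameter_code for c in self if flag in c.flags]

    def to_frame(self) -> pd.DataFrame:
        """Serialise to the registry schema (printed-column orientation kept
        canonical; ``c`` empty for 2-coefficient families)."""
        rows = []
        for curve in self:
            coef = list(curve.coefficients) + [math.nan] * (3 - len(curve.coefficients))
            rows.append(
                {
                    "parameter_code": curve.parameter_code,
                    "description": curve.description,
                    "family": curve.family.value,
                    "a": coef[0],
                    "b": coef[1],
                    "c": coef[2],
                    "r_squared": curve.r_squared,
                    "flags": ";".join(sorted(curve.flags)),
                }
            )
        return pd.DataFrame(rows)


def _parse_row(row: pd.Series) -> ResponseCurve:
    code = str(row["parameter_code"])
    try:
        family = ResponseFamily(str(row["family"]))
    except ValueError:
        raise SchemaError(f"row {code!r}: unknown family {row['family']!r}") from None

    printed = [row.get("a"), row.get("b"), row.get("c")]
    printed = [float(v) for v in printed if v is not None and not pd.isna(v)]
    if len(printed) != family.arity:
        raise SchemaError(
            f"row {code!r}: family {family.value} expects {family.arity} "
            f"coefficients, found {len(printed)}"
        )

    flags: set[str] = set()
    if family is ResponseFamily.LINEAR:
        slope, intercept, swapped = disambiguate_linear(printed[0], printed[1])
        if swapped:
            flags.add(FLAG_COLUMN_SWAPPED)
        if abs(intercept - 1.0) > INTERCEPT_ANOMALY_TOL:
            flags.add(FLAG_INTERCEPT_ANOMALY)
        trend = str(row.get("trend", "")).strip()
        if (trend == "dec" and slope > 0) or (trend == "inc" and slope < 0):
            flags.add(FLAG_DIRECTION_CONFLICT)
        coefficients = (slope, intercept)
    else:
        coefficients = tuple(printed)

    r2 = row.get("r_squared")
    r2 = None if r2 is None or pd.isna(r2) else float(r2)
    return ResponseCurve(
        parameter_code=code,
        description=str(row.get("description", "")),
        family=family,
        coefficients=coefficients,
        r_squared=r2,
        flags=frozenset(flags),
    )


def load_registry(source=None) -> CurveRegistry:
    """Load a curve registry from a CSV path, or the packaged table if None.

    The file schema is ``parameter_code, description, family, a, b, c,
    r_squared[, trend]`` with ``#`` comment lines; coefficients are stored as
    printed and linear rows are disambiguated on load.
    """
    if source is None:
        ref = importlib.resources.files("cottonwl.data") / "response_curves.csv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, comment="#")
        version = REGISTRY_VERSION
    else:
        df = pd.read_csv(source, comment="#")
        version = "user"

    required = {"parameter_code", "family", "a", "b"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"registry file missing columns: {sorted(missing)}")

    entries: dict[str, ResponseCurve] = {}
    for _, row in df.iterrows():
        curve = _parse_row(row)
        if curve.parameter_code in entries:
            raise SchemaError(f"duplicate parameter_code {curve.parameter_code!r}")
        entries[curve.parameter_code] = curve
    return CurveRegistry(entries=entries, version=version)
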