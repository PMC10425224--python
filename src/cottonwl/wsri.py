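"""Treatment means and the waterlogging stress response index (WSRI).

The WSRI normalises each measured parameter to a dimensionless scale by
dividing its treatment mean by the mean of the same parameter in the 0-day
(control) treatment: 1 means waterlogging is not limiting, 0 means fully
limiting. Values above 1 occur for stress-induced traits (flavonoids,
anthocyanins, NPQ) and are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ControlMeanError, SchemaError

TABLE_COLUMNS = ["duration", "replicate", "parameter", "value"]


@dataclass
class TreatmentTable:
    """Long-format replicate-level measurements.

    One row per (duration in days, replicate id, parameter code) with the
    measured value in the parameter's native units.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise SchemaError(f"treatment table missing columns: {sorted(missing)}")
        values = self.data["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise SchemaError("treatment table contains non-finite values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def durations(self) -> list[int]:
        return sorted(int(d) for d in self.data["duration"].unique())

    @property
    def parameters(self) -> list[str]:
        return sorted(self.data["parameter"].unique())

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "TreatmentTable":
        return cls(pd.DataFrame(list(records), columns=TABLE_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> "TreatmentTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path, metadata: Mapping[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            for key, val in (metadata or {}).items():
                fh.write(f"# {key}: {val}\n")
            self.data.to_csv(fh, index=False)


@dataclass
class WsriTable:
    """Per-parameter, per-duration stress indices plus the control means."""

    entries: pd.DataFrame  # columns: parameter, duration, index
    control_means: dict[str, float] = field(default_factory=dict)
    cell_sd: pd.DataFrame | None = None  # replicate dispersion per cell

    def index_of(self, parameter: str, duration: float) -> float:
        sel = self.entries[
            (self.entries["parameter"] == parameter)
            & (self.entries["duration"] == duration)
        ]
        if sel.empty:
            raise KeyError((parameter, duration))
        return float(sel["index"].iloc[0])

    def points(self, parameter: str) -> tuple[np.ndarray, np.ndarray]:
        """Ordered (durations, indices) arrays for one parameter."""
        sel = self.entries[self.entries["parameter"] == parameter].sort_values("duration")
        if sel.empty:
            raise KeyError(parameter)
        return sel["duration"].to_numpy(float), sel["index"].to_numpy(float)

    @property
    def parameters(self) -> list[str]:
        return sorted(self.entries["parameter"].unique())

    def to_csv(self, path, metadata: Mapping[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            for key, val in (metadata or {}).items():
                fh.write(f"# {key}: {val}\n")
            self.entries.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "WsriTable":
        df = pd.read_csv(path, comment="#")
        return cls(entries=df)


def treatment_means(table: TreatmentTable) -> pd.Series:
    """Arithmetic mean per (parameter, duration) cell.

    Missing cells are absent from the output, never zero-filled.
    """
    if len(table) == 0:
        return pd.Series(dtype=float)
    return table.data.groupby(["parameter", "duration"])["value"].mean()


def compute_wsri(table: TreatmentTable) -> WsriTable:
    """Normalise treatment means by each parameter's 0-day control mean.

    The index at duration 0 is mean/mean of the identical cell and is
    therefore exactly 1 for every parameter. Negative measurements yield
    negative indices, retained with a warning.
    """
    means = treatment_means(table)
    sds = table.data.groupby(["parameter", "duration"])["value"].std(ddof=1)

    rows = []
    control: dict[str, float] = {}
    for parameter in table.parameters:
        cell = means.loc[parameter]
        if 0 not in cell.index:
            raise ControlMeanError(f"parameter {parameter!r} has no 0-day control cell")
        c0 = float(cell.loc[0])
        if c0 == 0.0:
            raise ControlMeanError(f"parameter {parameter!r} has zero control mean")
        control[parameter] = c0
        for duration, mean in cell.items():
            index = float(mean) / c0
            if index < 0:
                warnings.warn(
                    f"negative index {index:.4g} for {parameter!r} at "
                    f"duration {duration}; retained",
                    stacklevel=2,
                )
            rows.append({"parameter": parameter, "duration": duration, "index": index})

    entries = pd.DataFrame(rows, columns=["parameter", "duration", "index"])
    return WsriTable(entries=entries, control_means=control, cell_sd=sds.reset_index())


@dataclass
class DesignReport:
    """Deviations of a treatment table from the expected factorial design."""

    missing_cells: list[tuple[str, int]]
    replicate_deviations: list[tuple[str, int, int]]  # (parameter, duration, n_found)
    duplicate_keys: list[tuple]

    @property
    def ok(self) -> bool:
        return not (self.missing_cells or self.replicate_deviations or self.duplicate_keys)


def validate_design(
    table: TreatmentTable,
    expected_durations: Iterable[int] = (0, 2, 4, 6, 8, 10, 12, 14),
    expected_reps: int = 5,
) -> DesignReport:
    """Report missing cells, replicate-count deviations and duplicate keys
    relative to the full factorial design (default: 8 treatments x 5 reps)."""
    expected = sorted(int(d) for d in expected_durations)
    counts = table.data.groupby(["parameter", "duration"]).size()

    missing, deviations = [], []
    for parameter in table.parameters:
        have = counts.loc[parameter] if parameter in counts.index else pd.Series(dtype=int)
        for d in expected:
            if d not in have.index:
                missing.append((parameter, d))
            elif int(have.loc[d]) != expected_reps:
                deviations.append((parameter, d, int(have.loc[d])))

    dup_mask = table.data.duplicated(subset=["duration", "replicate", "parameter"], keep=False)
    duplicates = sorted(
        {
            (int(r.duration), r.replicate, r.parameter)
            for r in table.data[dup_mask].itertuples()
        }
    )
    return DesignReport(missing, deviations, duplicates)
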