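"""Plate-level data model, I/O and per-cell normalization.

The screen measures two fluorescence channels per well: a lipid-droplet
(LD) stain and a cell stain used to enumerate cells.  Lipid storage is
quantified as LD signal per cell, then expressed as percent activity on a
control-anchored scale where the neutral (solvent) controls define 0 and
the positive-control (full inhibition) level defines -100.  Each compound
is tested as a multi-point titration; this module turns raw plate tables
into one :class:`TitrationSeries` per compound.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "WellRecord",
    "PlateControls",
    "TitrationSeries",
    "SchemaError",
    "RowValidationError",
    "read_plate_table",
    "write_plate_table",
    "read_pubchem_cr_table",
    "make_titration_concentrations",
    "ld_per_cell",
    "percent_activity",
    "compute_plate_controls",
    "assemble_titrations",
]

PLATE_TABLE_COLUMNS = (
    "plate",
    "well",
    "compound_id",
    "role",
    "concentration_molar",
    "ld_signal",
    "cell_signal",
)


class Role(str, Enum):
    """Function of a well on the plate."""

    SAMPLE = "sample"
    NEUTRAL_CONTROL = "neutral_control"
    POSITIVE_CONTROL = "positive_control"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowValidationError(ValueError):
    """A data row violates a field constraint; carries the row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class WellRecord:
    """One well's raw signals plus compound/role/concentration metadata."""

    plate_id: str
    well_id: str
    compound_id: str
    role: Role
    concentration: float  # molar
    ld_signal: float
    cell_signal: float

    def __post_init__(self):
        for name in ("concentration", "ld_signal", "cell_signal"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if self.role is Role.SAMPLE:
            if not self.compound_id:
                raise ValueError("sample well requires a compound_id")
            if not self.concentration > 0:
                raise ValueError("sample well requires concentration > 0")
        for name in ("ld_signal", "cell_signal"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class PlateControls:
    """Per-plate control summary for the LD-per-cell channel.

    Medians are used as the location summary (robust to single bad control
    wells); the MAD of the neutral wells is kept for QC only.
    """

    neutral_median: float
    positive_median: float
    neutral_mad: float
    n_neutral: int
    n_positive: int

    def __post_init__(self):
        if self.n_neutral < 1 or self.n_positive < 1:
            raise ValueError("need at least one neutral and one positive control well")
        if self.neutral_median == self.positive_median:
            raise ValueError(
                "neutral and positive control medians coincide; "
                "percent-activity normalization is undefined"
            )


@dataclass
class TitrationSeries:
    """Ordered (concentration, percent-activity) points for one compound.

    ``activity`` is on the control-anchored scale (0 = neutral, -100 = the
    positive-control level); ``cell_activity`` is the percent change of the
    cell signal relative to the plate's neutral wells, used for the
    cytotoxicity counter-screen.  ``mask`` marks points excluded from
    fitting (unevaluable wells or a single outlier).
    """

    compound_id: str
    concentrations: np.ndarray  # molar, strictly increasing
    activity: np.ndarray  # percent
    cell_activity: np.ndarray  # percent
    mask: np.ndarray  # bool, True = excluded

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.cell_activity = np.asarray(self.cell_activity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.concentrations)
        if not (len(self.activity) == len(self.cell_activity) == len(self.mask) == n):
            raise ValueError("all per-point arrays must share one length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def unmasked(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.mask
        return self.concentrations[keep], self.activity[keep]

    def with_mask(self, mask: np.ndarray) -> "TitrationSeries":
        return replace(self, mask=np.asarray(mask, dtype=bool).copy())


def make_titration_concentrations(top: float, ratio: float, n_points: int) -> np.ndarray:
    """Geometric dilution series ``top, top/ratio, ...`` in increasing order.

    The screen's standard grid is ``make_titration_concentrations(46e-6, 5, 7)``:
    46 uM down to ~2.94 nM in 1:5 steps.
    """
    if n_points < 2:
        raise ValueError("a titration needs at least 2 concentrations")
    if not top > 0:
        raise ValueError("top concentration must be positive")
    if not ratio > 1:
        raise ValueError("dilution ratio must exceed 1")
    conc = top / ratio ** np.arange(n_points - 1, -1, -1, dtype=float)
    return conc


def ld_per_cell(ld_signal: float, cell_signal: float) -> float:
    """LD signal normalized to the cell signal; NaN flags an unevaluable well.

    A well with no detectable cells cannot be phenotyped, so a non-positive
    cell signal yields NaN rather than raising; downstream assembly masks
    such points instead of aborting the pipeline.
    """
    if cell_signal <= 0:
        return float("nan")
    return ld_signal / cell_signal


def percent_activity(x: float | np.ndarray, controls: PlateControls) -> float | np.ndarray:
    """Control-anchored percent activity.

    ``100 * (x - neutral) / (neutral - positive)``: 0 at the neutral median,
    -100 at the positive-control median, affine-equivariant in x.
    """
    denom = controls.neutral_median - controls.positive_median
    if isinstance(x, np.ndarray):
        return 100.0 * (x - controls.neutral_median) / denom
    return 100.0 * (float(x) - controls.neutral_median) / denom


def _parse_row(idx: int, row: dict) -> WellRecord:
    try:
        role = Role(row["role"].strip())
    except ValueError as e:
        raise RowValidationError(idx, f"unknown role {row['role']!r}") from e
    try:
        conc = float(row["concentration_molar"])
        ld = float(row["ld_signal"])
        cell = float(row["cell_signal"])
    except ValueError as e:
        raise RowValidationError(idx, str(e)) from e
    try:
        return WellRecord(
            plate_id=row["plate"].strip(),
            well_id=row["well"].strip(),
            compound_id=row["compound_id"].strip(),
            role=role,
            concentration=conc,
            ld_signal=ld,
            cell_signal=cell,
        )
    except ValueError as e:
        raise RowValidationError(idx, str(e)) from e


def read_plate_table(path_or_stream) -> list[WellRecord]:
    """Read a plate table CSV into :class:`WellRecord` rows, order preserved.

    Required header columns: plate, well, compound_id, role,
    concentration_molar, ld_signal, cell_signal.  Extra columns are ignored.
    """
    if hasattr(path_or_stream, "read"):
        return _read_plate_stream(path_or_stream)
    with open(path_or_stream, newline="") as fh:
        return _read_plate_stream(fh)


def _read_plate_stream(fh) -> list[WellRecord]:
    reader = csv.DictReader(fh)
    header = reader.fieldnames or []
    missing = [c for c in PLATE_TABLE_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"plate table missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(reader, start=2):  # header is line 1
        records.append(_parse_row(i, row))
    return records


def write_plate_table(records: Iterable[WellRecord], path_or_stream) -> None:
    """Write records in the canonical plate-table CSV schema (round-trips
    with :func:`read_plate_table`)."""
    own = not hasattr(path_or_stream, "write")
    fh = open(path_or_stream, "w", newline="") if own else path_or_stream
    try:
        w = csv.writer(fh)
        w.writerow(PLATE_TABLE_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.plate_id,
                    r.well_id,
                    r.compound_id,
                    r.role.value,
                    repr(r.concentration),
                    repr(r.ld_signal),
                    repr(r.cell_signal),
                ]
            )
    finally:
        if own:
            fh.close()


def read_pubchem_cr_table(
    path_or_stream,
    column_to_molar: dict[str, float],
    id_column: str = "PUBCHEM_SID",
) -> list[TitrationSeries]:
    """Ingest a PubChem BioAssay concentration-response export.

    Those exports are wide tables with one percent-activity column per tested
    concentration; ``column_to_molar`` maps each activity column name to its
    molar concentration.  Activities are assumed to be already on a
    control-anchored percent scale; missing cells become masked points only
    when a full row is otherwise usable, otherwise they are dropped.
    """
    df = pd.read_csv(path_or_stream)
    if id_column not in df.columns:
        raise SchemaError(f"PubChem table missing id column {id_column!r}")
    missing = [c for c in column_to_molar if c not in df.columns]
    if missing:
        raise SchemaError(f"PubChem table missing activity column(s): {', '.join(missing)}")
    cols = sorted(column_to_molar, key=column_to_molar.__getitem__)
    conc = np.array([column_to_molar[c] for c in cols], dtype=float)
    series = []
    for _, row in df.iterrows():
        act = row[cols].to_numpy(dtype=float)
        keep = np.isfinite(act)
        if keep.sum() < 2:
            continue
        series.append(
            TitrationSeries(
                compound_id=str(row[id_column]),
                concentrations=conc[keep],
                activity=act[keep],
                cell_activity=np.zeros(int(keep.sum())),
                mask=np.zeros(int(keep.sum()), dtype=bool),
            )
        )
    return series


def compute_plate_controls(records: Sequence[WellRecord]) -> dict[str, PlateControls]:
    """Per-plate control summaries on the LD-per-cell scale.

    Raises if any plate carrying sample wells lacks neutral or positive
    control wells.
    """
    by_plate: dict[str, dict[Role, list[float]]] = {}
    plates_with_samples = set()
    for r in records:
        d = by_plate.setdefault(r.plate_id, {Role.NEUTRAL_CONTROL: [], Role.POSITIVE_CONTROL: []})
        if r.role is Role.SAMPLE:
            plates_with_samples.add(r.plate_id)
        else:
            v = ld_per_cell(r.ld_signal, r.cell_signal)
            if math.isfinite(v):
                d[r.role].append(v)
    out = {}
    missing = []
    for plate, d in by_plate.items():
        neu, pos = d[Role.NEUTRAL_CONTROL], d[Role.POSITIVE_CONTROL]
        if not neu or not pos:
            if plate in plates_with_samples:
                missing.append(plate)
            continue
        neu_arr = np.asarray(neu)
        med = float(np.median(neu_arr))
        out[plate] = PlateControls(
            neutral_median=med,
            positive_median=float(np.median(pos)),
            neutral_mad=float(np.median(np.abs(neu_arr - med))),
            n_neutral=len(neu),
            n_positive=len(pos),
        )
    if missing:
        raise ValueError(
            "plate(s) without usable control wells: " + ", ".join(sorted(missing))
        )
    return out


def _cell_neutral_medians(records: Sequence[WellRecord]) -> dict[str, float]:
    acc: dict[str, list[float]] = {}
    for r in records:
        if r.role is Role.NEUTRAL_CONTROL:
            acc.setdefault(r.plate_id, []).append(r.cell_signal)
    return {p: float(np.median(v)) for p, v in acc.items()}


def assemble_titrations(
    records: Sequence[WellRecord],
    plate_controls_by_plate: dict[str, PlateControls] | None = None,
) -> list[TitrationSeries]:
    """Build one sorted :class:`TitrationSeries` per compound.

    Sample wells are normalized per plate against that plate's controls;
    replicate wells at the same (compound, concentration) collapse to their
    median activity.  Cell-channel activity is the percent change of the
    cell signal versus the plate's neutral-well cell median.  Wells with a
    non-positive cell signal become masked points.
    """
    if plate_controls_by_plate is None:
        plate_controls_by_plate = compute_plate_controls(records)
    cell_neutral = _cell_neutral_medians(records)

    per_compound: dict[str, dict[float, list[tuple[float, float, bool]]]] = {}
    for r in records:
        if r.role is not Role.SAMPLE:
            continue
        if r.plate_id not in plate_controls_by_plate:
            raise ValueError(f"no controls available for plate {r.plate_id!r}")
        controls = plate_controls_by_plate[r.plate_id]
        norm = ld_per_cell(r.ld_signal, r.cell_signal)
        if math.isfinite(norm):
            act = percent_activity(norm, controls)
            bad = False
        else:
            act = float("nan")
            bad = True
        cn = cell_neutral.get(r.plate_id)
        cell_act = 100.0 * (r.cell_signal - cn) / cn if cn else 0.0
        per_compound.setdefault(r.compound_id, {}).setdefault(r.concentration, []).append(
            (act, cell_act, bad)
        )

    out = []
    for compound_id in per_compound:
        by_conc = per_compound[compound_id]
        conc = np.array(sorted(by_conc), dtype=float)
        activity, cell_activity, mask = [], [], []
        for c in conc:
            pts = by_conc[c]
            good = [p for p in pts if not p[2]]
            if good:
                activity.append(float(np.median([p[0] for p in good])))
                cell_activity.append(float(np.median([p[1] for p in good])))
                mask.append(False)
            else:
                activity.append(0.0)
                cell_activity.append(0.0)
                mask.append(True)
        out.append(
            TitrationSeries(
                compound_id=compound_id,
                concentrations=conc,
                activity=np.array(activity),
                cell_activity=np.array(cell_activity),
                mask=np.array(mask, dtype=bool),
            )
        )
    return out
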