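"""Data model and I/O for 384-spot agar cell arrays.

A screen consists of *deletion arrays* (384-position plates carrying one
gene-deletion strain per spot) replicated onto media at several drug
concentrations, each paired with a matched *reference array* -- a full
384-spot plate of the wild-type reference strain whose CPP standard
deviation is the z-score denominator downstream.

Canonical interchange format is long (tidy) TSV; CSV is accepted via the
``dialect`` argument. Positions follow the standard 384-well convention:
rows A-P (1-16), columns 1-24.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLS = 24
N_POSITIONS = N_ROWS * N_COLS

TIMESERIES_COLUMNS = ["plate", "row", "col", "strain", "condition_ugml", "time_h", "intensity"]
LAYOUT_COLUMNS = ["plate", "row", "col", "strain", "role"]
MANIFEST_COLUMNS = ["array_id", "condition_ugml", "deletion_plate", "reference_plate"]

ROLES = {"deletion", "reference", "empty"}


class SchemaError(ValueError):
    """A table is missing required columns or violates the format contract."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the offending line."""


def position_to_rc(position: str) -> tuple[int, int]:
    """Parse ``"A1".."P24"`` into 1-based (row, col)."""
    if not position or position[0].upper() not in ROW_LETTERS:
        raise ParseError(f"invalid position {position!r}: row letter must be A-P")
    row = ROW_LETTERS.index(position[0].upper()) + 1
    try:
        col = int(position[1:])
    except ValueError:
        raise ParseError(f"invalid position {position!r}: column must be an integer") from None
    if not 1 <= col <= N_COLS:
        raise ParseError(f"invalid position {position!r}: column must be 1-{N_COLS}")
    return row, col


def rc_to_position(row: int, col: int) -> str:
    """Format 1-based (row, col) as ``"A1".."P24"``."""
    if not 1 <= row <= N_ROWS or not 1 <= col <= N_COLS:
        raise ValueError(f"(row, col) = ({row}, {col}) outside the 16x24 array")
    return f"{ROW_LETTERS[row - 1]}{col}"


@dataclass(frozen=True)
class SpotTimeSeries:
    """One spot culture's (time, intensity) observations.

    Attributes
    ----------
    plate_id : str
        Physical plate identifier.
    row, col : int
        1-based array position (rows A-P map to 1-16).
    strain_id : str
        ORF/gene name of the deletion strain, or the reference marker.
    condition : float
        Drug concentration in ug/mL.
    times, intensities : ndarray
        Observation times in hours (strictly increasing, >= 0) and
        average pixel intensities (arbitrary units, >= 0).
    """

    plate_id: str
    row: int
    col: int
    strain_id: str
    condition: float
    times: np.ndarray
    intensities: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if t.size and t.min() < 0:
            raise ValueError("observation times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"times must be strictly increasing for spot {self.plate_id}:{self.position}"
            )
        if y.size and y.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def position(self) -> str:
        return rc_to_position(self.row, self.col)

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class PlateLayout:
    """Mapping from the 384 array positions to strain identity and role.

    ``positions`` maps 1-based (row, col) to ``(strain_id, role)`` where
    role is one of ``deletion``, ``reference`` or ``empty``.
    """

    plate_id: str
    positions: dict[tuple[int, int], tuple[str, str]]

    def validate(self) -> list[str]:
        issues: list[str] = []
        if len(self.positions) != N_POSITIONS:
            issues.append(
                f"layout {self.plate_id} has {len(self.positions)} positions, expected {N_POSITIONS}"
            )
        for (r, c), (strain, role) in self.positions.items():
            if not (1 <= r <= N_ROWS and 1 <= c <= N_COLS):
                issues.append(f"layout {self.plate_id}: position ({r},{c}) out of range")
            if role not in ROLES:
                issues.append(f"layout {self.plate_id}: unknown role {role!r} at ({r},{c})")
        return issues

    @property
    def is_reference(self) -> bool:
        roles = {role for _, role in self.positions.values()}
        return roles <= {"reference", "empty"} and "reference" in roles

    def strain_at(self, row: int, col: int) -> str:
        return self.positions[(row, col)][0]


@dataclass
class ScreenDesign:
    """Concentration ladder plus the manifest pairing arrays to plates.

    The manifest has one row per (array_id, condition) giving the physical
    deletion plate and its matched reference plate. Reference arrays are
    matched explicitly, never inferred. Concentration index 1 is untreated
    (0 ug/mL) by construction.
    """

    concentrations: tuple[float, ...]
    manifest: pd.DataFrame  # columns MANIFEST_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.manifest.columns]
        if missing:
            raise SchemaError(f"manifest missing required columns: {missing}")
        if not self.concentrations or self.concentrations[0] != 0:
            raise ValueError("concentration index 1 must be untreated (0 ug/mL)")

    def concentration_index(self, condition: float) -> int:
        """1-based index of ``condition`` in the design ladder."""
        for i, c in enumerate(self.concentrations, start=1):
            if np.isclose(c, condition):
                return i
        raise KeyError(f"condition {condition} not in design {self.concentrations}")

    @property
    def array_ids(self) -> list[str]:
        return sorted(self.manifest["array_id"].unique())


@dataclass
class ValidationReport:
    issues: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues


def _read_df(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    sep = {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    return pd.read_csv(path, sep=sep, comment="#", dtype={"plate": str, "strain": str},
                       float_precision="round_trip")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str], what: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 1-based
            raise ParseError(f"{what}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_timeseries(path: str | Path, dialect: str = "tsv") -> list[SpotTimeSeries]:
    """Read a long-format spot-intensity table into SpotTimeSeries records.

    One record is produced per unique (plate, position, condition); rows are
    grouped and time-sorted. Unknown columns are preserved in ``metadata``.
    """
    df = _read_df(path, dialect)
    _require_columns(df, TIMESERIES_COLUMNS, f"time-series table {path}")
    df = _coerce_numeric(df, ["row", "col", "condition_ugml", "time_h", "intensity"], str(path))
    dup = df.duplicated(subset=["plate", "row", "col", "condition_ugml", "time_h"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ParseError(
            "duplicate observation for spot "
            f"{first['plate']}:{rc_to_position(int(first['row']), int(first['col']))} "
            f"at t={first['time_h']} h"
        )
    extra = [c for c in df.columns if c not in TIMESERIES_COLUMNS]
    out: list[SpotTimeSeries] = []
    for (plate, row, col, cond), grp in df.groupby(
        ["plate", "row", "col", "condition_ugml"], sort=True
    ):
        grp = grp.sort_values("time_h")
        meta = {c: grp[c].iloc[0] for c in extra}
        out.append(
            SpotTimeSeries(
                plate_id=str(plate),
                row=int(row),
                col=int(col),
                strain_id=str(grp["strain"].iloc[0]),
                condition=float(cond),
                times=grp["time_h"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                metadata=meta,
            )
        )
    return out


def timeseries_to_frame(series: Iterable[SpotTimeSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, y in zip(s.times, s.intensities):
            rows.append((s.plate_id, s.row, s.col, s.strain_id, s.condition, t, y))
    return pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)


def write_timeseries(series: Iterable[SpotTimeSeries], path: str | Path,
                     dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    timeseries_to_frame(series).to_csv(path, sep=sep, index=False)


def read_layouts(path: str | Path, dialect: str = "tsv") -> dict[str, PlateLayout]:
    """Read one or more plate layouts from a long TSV (plate, row, col, strain, role)."""
    df = _read_df(path, dialect)
    _require_columns(df, LAYOUT_COLUMNS, f"layout table {path}")
    df = _coerce_numeric(df, ["row", "col"], str(path))
    layouts = {}
    for plate, grp in df.groupby("plate"):
        positions = {
            (int(r.row), int(r.col)): (str(r.strain), str(r.role)) for r in grp.itertuples()
        }
        if len(positions) != len(grp):
            raise ParseError(f"layout {plate}: duplicated position")
        layouts[str(plate)] = PlateLayout(plate_id=str(plate), positions=positions)
    return layouts


def write_layouts(layouts: Mapping[str, PlateLayout], path: str | Path) -> None:
    rows = []
    for layout in layouts.values():
        for (r, c), (strain, role) in sorted(layout.positions.items()):
            rows.append((layout.plate_id, r, c, strain, role))
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path, dialect: str = "tsv") -> ScreenDesign:
    """Read the screen manifest; the concentration ladder is its sorted unique set."""
    df = _read_df(path, dialect)
    _require_columns(df, MANIFEST_COLUMNS, f"manifest {path}")
    df = _coerce_numeric(df, ["condition_ugml"], str(path))
    concs = tuple(sorted(df["condition_ugml"].unique()))
    return ScreenDesign(concentrations=concs, manifest=df.reset_index(drop=True))


def write_design(design: ScreenDesign, path: str | Path) -> None:
    design.manifest.to_csv(path, sep="\t", index=False)


def validate_design(
    design: ScreenDesign,
    layouts: Mapping[str, PlateLayout],
    series: Sequence[SpotTimeSeries] | None = None,
) -> ValidationReport:
    """Report-only consistency check of a screen before scoring.

    Flags deletion arrays missing a design condition, missing matched
    reference arrays/layouts, malformed layouts, and (when ``series`` is
    given) plate positions without any observations. Scoring refuses
    arrays flagged here.
    """
    issues: list[str] = []
    man = design.manifest
    for array_id, grp in man.groupby("array_id"):
        have = set(grp["condition_ugml"])
        for conc in design.concentrations:
            if not any(np.isclose(conc, h) for h in have):
                issues.append(f"array {array_id}: missing condition {conc} ug/mL")
    for rec in man.itertuples():
        for plate, kind in ((rec.deletion_plate, "deletion"), (rec.reference_plate, "reference")):
            if plate not in layouts:
                issues.append(f"array {rec.array_id}: no layout for {kind} plate {plate}")
    for layout in layouts.values():
        issues.extend(layout.validate())
    if series is not None:
        seen: dict[str, set[tuple[int, int]]] = {}
        for s in series:
            seen.setdefault(s.plate_id, set()).add((s.row, s.col))
        used_plates = set(man["deletion_plate"]) | set(man["reference_plate"])
        for plate in sorted(used_plates):
            layout = layouts.get(plate)
            if layout is None:
                continue
            expect = {
                pos for pos, (_, role) in layout.positions.items() if role != "empty"
            }
            missing = expect - seen.get(plate, set())
            if missing:
                r, c = sorted(missing)[0]
                issues.append(
                    f"plate {plate}: {len(missing)} positions without data "
                    f"(first {rc_to_position(r, c)})"
                )
    return ValidationReport(issues=issues)


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a result table as TSV with a header comment recording provenance."""
    from . import __version__

    buf = io.StringIO()
    seed_part = f" seed={seed}" if seed is not None else ""
    buf.write(f"# qhtcp {__version__}{seed_part}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
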