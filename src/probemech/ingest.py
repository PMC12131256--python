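"""Reading and validating bending traces and sample metadata.

All quantities are normalised to strict SI (metres, newtons, pascals) at the
I/O boundary; every downstream module assumes SI. Trace files are two-column
delimited text (delimiter sniffed, optional header); metadata is a delimited
table whose dimension columns may be in field units (``_mm``/``_cm`` suffixes)
or in canonical SI (``_m`` suffixes).
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Geometry",
    "BendingTrace",
    "CrossSection",
    "SampleRecord",
    "IngestError",
    "read_trace",
    "read_metadata",
    "records_to_frame",
    "frame_to_records",
    "write_records",
    "read_records",
]

MATERIAL_TYPES = ("twig", "vine", "bark", "grass")
PREFERENCE_LEVELS = ("most_preferred", "less_preferred", "never_used")

_LENGTH_FACTORS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6}
_FORCE_FACTORS = {"N": 1.0, "kN": 1e3, "mN": 1e-3}


class IngestError(ValueError):
    """Malformed input file or metadata record."""


@dataclass(frozen=True)
class Geometry:
    """Four-point rig geometry: support span ``L`` and probe offset ``a`` (m)."""

    span_L: float
    offset_a: float

    def __post_init__(self) -> None:
        if not (self.span_L > 0 and math.isfinite(self.span_L)):
            raise IngestError(f"span_L must be positive, got {self.span_L}")
        if not (0 < self.offset_a <= self.span_L / 2):
            raise IngestError(
                f"offset_a must satisfy 0 < a <= L/2, got a={self.offset_a}, L={self.span_L}"
            )


@dataclass
class BendingTrace:
    """One sample's ordered force-displacement series plus rig geometry.

    ``displacement`` is strictly increasing (m); ``force`` is finite (N).
    """

    sample_id: str
    displacement: np.ndarray
    force: np.ndarray
    span_L: float
    offset_a: float

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.ndim != 1 or self.force.ndim != 1:
            raise IngestError("trace series must be one-dimensional")
        if len(self.displacement) != len(self.force):
            raise IngestError("displacement and force series differ in length")
        if len(self.displacement) < 2:
            raise IngestError("insufficient points: a trace needs at least 2 rows")
        if not np.all(np.isfinite(self.displacement)) or not np.all(np.isfinite(self.force)):
            raise IngestError("trace contains non-finite values")
        if np.any(np.diff(self.displacement) <= 0):
            raise IngestError("displacement must be strictly increasing after cleanup")
        Geometry(self.span_L, self.offset_a)  # validates

    def __len__(self) -> int:
        return len(self.displacement)


@dataclass(frozen=True)
class CrossSection:
    """Regular cross-section: circular (radius) or rectangular (width, depth), in m."""

    shape: str
    radius: float | None = None
    width: float | None = None
    depth: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "circular":
            if self.radius is None or not self.radius > 0:
                raise IngestError("circular section requires positive radius")
            if self.width is not None or self.depth is not None:
                raise IngestError("circular section must not set width/depth")
        elif self.shape == "rectangular":
            if self.width is None or self.depth is None:
                raise IngestError("rectangular section requires width and depth")
            if not (self.width > 0 and self.depth > 0):
                raise IngestError("rectangular dimensions must be positive")
            if self.radius is not None:
                raise IngestError("rectangular section must not set radius")
        else:
            raise IngestError(f"unknown cross-section shape: {self.shape!r}")

    def second_moment(self) -> float:
        # local import avoids a cycle; mechanics owns the formulas
        from . import mechanics

        if self.shape == "circular":
            return mechanics.second_moment_circular(self.radius)
        return mechanics.second_moment_rectangular(self.width, self.depth)


@dataclass
class SampleRecord:
    """One tested sample: metadata plus (once computed) derived EI / E and QC flag."""

    sample_id: str
    plant_id: str
    species: str
    mound_id: str
    plant_part: str
    material_type: str
    section: CrossSection
    length: float
    tool_source_species: bool
    preference: str
    plant_used: bool
    EI: float | None = None
    E: float | None = None
    qc_pass: bool | None = None

    def __post_init__(self) -> None:
        if self.material_type not in MATERIAL_TYPES:
            raise IngestError(f"unknown material type: {self.material_type!r}")
        if self.preference not in PREFERENCE_LEVELS:
            raise IngestError(f"unknown preference level: {self.preference!r}")
        if self.preference == "never_used" and self.tool_source_species:
            raise IngestError(
                f"{self.sample_id}: preference 'never_used' requires tool_source_species=False"
            )
        if not self.length > 0:
            raise IngestError(f"{self.sample_id}: length must be positive")
        if self.EI is not None and self.E is not None:
            expected = self.E * self.section.second_moment()
            if abs(self.EI - expected) > 1e-9 * max(abs(self.EI), abs(expected), 1e-300):
                raise IngestError(f"{self.sample_id}: EI inconsistent with E * I(section)")


# ---------------------------------------------------------------------------
# trace files


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Delimiter-sniffed read with optional header row; '#' starts a comment."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise IngestError(f"{path}: empty file")
    # dtype=str: numeric conversion is done by the callers with numpy/python
    # parsing, which (unlike the pandas fast parser) is correctly rounded
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(lines)), sep=None, engine="python", header=None, dtype=str
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise IngestError(f"{path}: could not parse delimited text ({exc})") from exc
    # header detection: a first row that does not convert to float
    first = df.iloc[0]
    try:
        first.astype(float)
        has_header = False
    except (ValueError, TypeError):
        has_header = True
    if has_header:
        df = pd.read_csv(
            io.StringIO("\n".join(lines)), sep=None, engine="python", header=0, dtype=str
        )
    return df


def read_trace(
    path: str | os.PathLike,
    geometry: Geometry,
    displacement_unit: str = "m",
    force_unit: str = "N",
    sample_id: str | None = None,
) -> BendingTrace:
    """Read a two-column force-displacement file and normalise it to SI.

    Column order is displacement then force. Rows are sorted by displacement
    and forces at exactly duplicated displacements are averaged (instrument
    jitter); anything else that breaks the trace invariants raises
    :class:`IngestError`.
    """
    if displacement_unit not in _LENGTH_FACTORS:
        raise IngestError(f"unknown displacement unit {displacement_unit!r}")
    if force_unit not in _FORCE_FACTORS:
        raise IngestError(f"unknown force unit {force_unit!r}")
    df = _read_table(path)
    if df.shape[1] < 2:
        raise IngestError(f"{path}: expected two numeric columns")
    try:
        disp = df.iloc[:, 0].astype(float).to_numpy()
        force = df.iloc[:, 1].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise IngestError(f"{path}: malformed numeric content ({exc})") from exc
    if len(disp) < 2:
        raise IngestError(f"{path}: insufficient points (need >= 2 rows)")
    disp = disp * _LENGTH_FACTORS[displacement_unit]
    force = force * _FORCE_FACTORS[force_unit]

    order = np.argsort(disp, kind="stable")
    disp, force = disp[order], force[order]
    # average forces at duplicated displacements
    uniq, inverse, counts = np.unique(disp, return_inverse=True, return_counts=True)
    if len(uniq) != len(disp):
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, force)
        force = summed / counts
        disp = uniq
    if len(disp) < 2:
        raise IngestError(f"{path}: insufficient points after duplicate averaging")

    sid = sample_id if sample_id is not None else os.path.splitext(os.path.basename(path))[0]
    return BendingTrace(
        sample_id=sid,
        displacement=disp,
        force=force,
        span_L=geometry.span_L,
        offset_a=geometry.offset_a,
    )


# ---------------------------------------------------------------------------
# metadata


_REQUIRED_META = [
    "sample_id",
    "plant_id",
    "species",
    "mound_id",
    "plant_part",
    "material_type",
    "tool_source_species",
    "preference",
    "plant_used",
]

_TRUTHY = {"true", "yes", "y", "1", "t"}
_FALSY = {"false", "no", "n", "0", "f"}


def _parse_bool(value, context: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise IngestError(f"{context}: cannot interpret {value!r} as boolean")


def _get_dim(row: pd.Series, stem: str) -> float | None:
    """Fetch a dimension in metres from either '<stem>_m' or a field-unit column."""
    for suffix, factor in (("_m", 1.0), ("_mm", 1e-3), ("_cm", 1e-2)):
        col = stem + suffix
        if col in row.index and pd.notna(row[col]):
            val = float(row[col])
            return val * factor
    return None


def read_metadata(path: str | os.PathLike) -> list[SampleRecord]:
    """Read a sample-metadata table into validated records (EI/E unset).

    The cross-section shape is inferred from which dimension columns are
    populated: a diameter implies circular, breadth+depth imply rectangular.
    A row with both set (or neither) is an error.
    """
    df = _read_table(path)
    if df.columns.dtype != object:
        raise IngestError(f"{path}: metadata table requires a header row")
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in _REQUIRED_META if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required columns: {missing}")
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        diameter = _get_dim(row, "diameter")
        breadth = _get_dim(row, "breadth")
        depth = _get_dim(row, "depth")
        if diameter is not None and (breadth is not None or depth is not None):
            raise IngestError(f"{sid}: both diameter and breadth/depth are set")
        if diameter is not None:
            section = CrossSection(shape="circular", radius=diameter / 2.0)
        elif breadth is not None and depth is not None:
            section = CrossSection(shape="rectangular", width=breadth, depth=depth)
        else:
            raise IngestError(f"{sid}: need either diameter or breadth+depth")
        length = _get_dim(row, "length")
        if length is None:
            raise IngestError(f"{sid}: missing length column (length_cm or length_m)")
        records.append(
            SampleRecord(
                sample_id=sid,
                plant_id=str(row["plant_id"]),
                species=str(row["species"]),
                mound_id=str(row["mound_id"]),
                plant_part=str(row["plant_part"]),
                material_type=str(row["material_type"]).strip().lower(),
                section=section,
                length=length,
                tool_source_species=_parse_bool(row["tool_source_species"], sid),
                preference=str(row["preference"]).strip().lower(),
                plant_used=_parse_bool(row["plant_used"], sid),
            )
        )
    return records


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Canonical SI table of records (dimension columns with ``_m`` suffixes)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "plant_id": r.plant_id,
                "species": r.species,
                "mound_id": r.mound_id,
                "plant_part": r.plant_part,
                "material_type": r.material_type,
                "diameter_m": 2 * r.section.radius if r.section.shape == "circular" else np.nan,
                "breadth_m": r.section.width if r.section.shape == "rectangular" else np.nan,
                "depth_m": r.section.depth if r.section.shape == "rectangular" else np.nan,
                "length_m": r.length,
                "tool_source_species": r.tool_source_species,
                "preference": r.preference,
                "plant_used": r.plant_used,
            }
        )
    return pd.DataFrame(rows)


def write_records(records: Iterable[SampleRecord], path: str | os.PathLike) -> None:
    """Write records in canonical SI form (bit-exact round trip via repr floats)."""
    df = records_to_frame(records)
    # %.17g guarantees a bit-exact float round trip
    df.to_csv(path, index=False, float_format="%.17g")


def read_records(path: str | os.PathLike) -> list[SampleRecord]:
    return read_metadata(path)
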