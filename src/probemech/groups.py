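"""Comparison schemes: assigning samples to the four grouping categorizations.

Each scheme partitions a defined subset of the records into labelled levels:

- ``tool_source``: all records, split by whether the species is a known tool
  source ("yes"/"no").
- ``preference``: all records, split into most_preferred / less_preferred /
  never_used species-preference ranks.
- ``plant_used``: tool-source-species records only, split by whether the
  individual plant bears removal scars ("used"/"not_used").
- ``material_type``: tool-source-species records, split by raw material
  (twig/vine/bark/grass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from .ingest import SampleRecord

__all__ = [
    "GroupScheme",
    "SchemeError",
    "SCHEME_NAMES",
    "assign_scheme",
    "classify_preference",
    "schemes_long_table",
]

# species-preference rank cut points on tool-assemblage frequency share
MOST_PREFERRED_SHARE = 0.117
LESS_PREFERRED_SHARE = 0.10


class SchemeError(ValueError):
    pass


@dataclass(frozen=True)
class GroupScheme:
    """A named categorization: ordered levels plus a per-sample assignment."""

    name: str
    levels: tuple[str, ...]
    assignment: dict[str, str]
    subset_rule: str

    def __post_init__(self) -> None:
        bad = {lv for lv in self.assignment.values() if lv not in self.levels}
        if bad:
            raise SchemeError(f"{self.name}: assignment uses undeclared levels {sorted(bad)}")

    def counts(self) -> dict[str, int]:
        out = {lv: 0 for lv in self.levels}
        for lv in self.assignment.values():
            out[lv] += 1
        return out

    @property
    def n(self) -> int:
        return len(self.assignment)


def _level_tool_source(r: SampleRecord) -> str:
    return "yes" if r.tool_source_species else "no"


def _level_preference(r: SampleRecord) -> str:
    return r.preference


def _level_plant_used(r: SampleRecord) -> str:
    return "used" if r.plant_used else "not_used"


def _level_material(r: SampleRecord) -> str:
    return r.material_type


_SCHEMES: dict[str, tuple[tuple[str, ...], Callable[[SampleRecord], bool], Callable, str]] = {
    "tool_source": (
        ("yes", "no"),
        lambda r: True,
        _level_tool_source,
        "all analysis records",
    ),
    "preference": (
        ("most_preferred", "less_preferred", "never_used"),
        lambda r: True,
        _level_preference,
        "all analysis records",
    ),
    "plant_used": (
        ("used", "not_used"),
        lambda r: r.tool_source_species,
        _level_plant_used,
        "tool-source-species records only",
    ),
    "material_type": (
        ("twig", "vine", "bark", "grass"),
        lambda r: r.tool_source_species,
        _level_material,
        "tool-source-species records only",
    ),
}

SCHEME_NAMES = tuple(_SCHEMES)


def assign_scheme(records: Iterable[SampleRecord], scheme_name: str) -> GroupScheme:
    """Assign each in-subset record to its level under the named scheme."""
    if scheme_name not in _SCHEMES:
        raise SchemeError(f"unknown scheme {scheme_name!r}; valid: {sorted(_SCHEMES)}")
    levels, subset, level_of, rule = _SCHEMES[scheme_name]
    assignment: dict[str, str] = {}
    for r in records:
        if not subset(r):
            continue
        lv = level_of(r)
        if lv not in levels:
            raise SchemeError(f"{r.sample_id}: level {lv!r} not valid for scheme {scheme_name}")
        if r.sample_id in assignment:
            raise SchemeError(f"duplicate sample_id {r.sample_id!r}")
        assignment[r.sample_id] = lv
    return GroupScheme(name=scheme_name, levels=levels, assignment=assignment, subset_rule=rule)


def classify_preference(tool_frequency_share: float, tool_source: bool = True) -> str:
    """Rank a species' preference from its share of recovered tools.

    Shares of at least 11.7% rank most_preferred; at most 10% rank
    less_preferred; a species that is not a tool source is never_used
    regardless of share. Shares falling strictly between the two cut points
    are unaddressed by the ranking rule and are conservatively classed
    less_preferred with a warning.
    """
    if not 0 <= tool_frequency_share <= 1:
        raise SchemeError(f"share must be in [0, 1], got {tool_frequency_share}")
    if not tool_source:
        return "never_used"
    if tool_frequency_share >= MOST_PREFERRED_SHARE:
        return "most_preferred"
    if tool_frequency_share <= LESS_PREFERRED_SHARE:
        return "less_preferred"
    warnings.warn(
        f"tool-frequency share {tool_frequency_share:.4f} falls between the "
        f"less-preferred ({LESS_PREFERRED_SHARE}) and most-preferred "
        f"({MOST_PREFERRED_SHARE}) cut points; classifying as less_preferred",
        stacklevel=2,
    )
    return "less_preferred"


def schemes_long_table(schemes: Sequence[GroupScheme]) -> pd.DataFrame:
    """Tidy long export: one row per (sample_id, scheme, level)."""
    rows = [
        {"sample_id": sid, "scheme": s.name, "level": lv}
        for s in schemes
        for sid, lv in s.assignment.items()
    ]
    return pd.DataFrame(rows, columns=["sample_id", "scheme", "level"])
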