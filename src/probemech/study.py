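"""Data-backed study evaluation: headline quantities from a processed table.

The deposited study data is not redistributable with this package; this
module consumes a processed per-sample table in the canonical metadata schema
(see :mod:`probemech.ingest`) augmented with derived columns ``EI_Nm2`` and
``E_Pa`` (or, when absent, per-sample trace files from which they are
computed). It recomputes the headline quantities: retained sample counts per
scheme, EI / E extrema, the tool-source type-II F on log EI, and the
median-basis percent rigidity differences.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .groups import assign_scheme
from .ingest import IngestError, frame_to_records, _read_table
from .mechanics import QC_THRESHOLD_PA, qc_filter
from .stats import (
    ModelSpec,
    build_analysis_frame,
    fit_group_model,
    percent_rigidity_difference,
)

__all__ = ["load_study_table", "compute_study_targets"]


def load_study_table(path: str | os.PathLike):
    """Read a processed study table and return records with EI/E attached."""
    df = _read_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("EI_Nm2", "E_Pa"):
        if col not in df.columns:
            raise IngestError(f"{path}: processed study table needs column {col}")
    records = frame_to_records(df)
    for rec, (_, row) in zip(records, df.iterrows()):
        rec.E = float(row["E_Pa"])
        rec.EI = float(row["EI_Nm2"])
    return records


def compute_study_targets(records) -> dict[str, float]:
    """Recompute the headline study quantities from parsed sample records.

    Keys follow the acceptance-target ids: counts (t1-t5), EI/E extrema
    (t6, t7), the tool-source F on log EI (t8) and median-basis percent
    rigidity differences (t9-t11).
    """
    retained, _ = qc_filter(records, QC_THRESHOLD_PA)
    out: dict[str, float] = {"t1": float(len(retained))}

    tool = assign_scheme(retained, "tool_source")
    out["t2"] = float(tool.counts()["yes"])
    pref = assign_scheme(retained, "preference")
    out["t3"] = float(pref.counts()["less_preferred"])
    used = assign_scheme(retained, "plant_used")
    out["t4"] = float(used.counts()["used"])
    mat = assign_scheme(retained, "material_type")
    out["t5"] = float(mat.counts()["twig"])

    eis = np.array([r.EI for r in retained])
    es = np.array([r.E for r in retained])
    out["t6"] = float(eis.max())
    out["t7"] = float(es.max() / 1e9)  # GPa

    frame = build_analysis_frame(retained, tool)
    res = fit_group_model(frame, ModelSpec(response="log_EI", scheme="tool_source"))
    scheme_row = res.f_table[res.f_table["term"] == "tool_source"]
    out["t8"] = float(scheme_row["F"].iloc[0])

    out["t9"] = percent_rigidity_difference(frame, "no", "yes", basis="median")
    pframe = build_analysis_frame(retained, pref)
    out["t10"] = percent_rigidity_difference(
        pframe, "most_preferred", "never_used", basis="median"
    )
    out["t11"] = percent_rigidity_difference(
        pframe, "most_preferred", "less_preferred", basis="median"
    )
    return out
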