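"""End-to-end orchestration: ingest -> mechanics -> groups -> stats -> report."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .groups import SCHEME_NAMES, assign_scheme, schemes_long_table
from .ingest import Geometry, SampleRecord, read_metadata, read_trace
from .mechanics import QC_THRESHOLD_PA, SlopeConfig, derive_quantities, qc_filter
from .stats import (
    MixedModelResult,
    ModelSpec,
    build_analysis_frame,
    fit_group_model,
    percent_rigidity_difference,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "analyze_records"]

log = logging.getLogger("probemech")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass(frozen=True)
class RunConfig:
    traces_dir: str
    metadata_path: str
    span_L: float
    offset_a: float
    out_dir: str
    schemes: tuple[str, ...] = SCHEME_NAMES
    slope: SlopeConfig = field(default_factory=SlopeConfig)
    qc_threshold_pa: float = QC_THRESHOLD_PA
    displacement_unit: str = "m"
    force_unit: str = "N"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not self.qc_threshold_pa > 0:
            raise PipelineError("config: QC threshold must be positive")
        if not self.schemes:
            raise PipelineError("config: at least one scheme must be requested")
        for s in self.schemes:
            if s not in SCHEME_NAMES:
                raise PipelineError(f"config: unknown scheme {s!r}")
        Geometry(self.span_L, self.offset_a)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


@_stage("ingest")
def _load(cfg: RunConfig):
    records = read_metadata(cfg.metadata_path)
    geometry = Geometry(cfg.span_L, cfg.offset_a)
    traces = {}
    for rec in records:
        path = os.path.join(cfg.traces_dir, f"{rec.sample_id}.csv")
        if not os.path.exists(path):
            path = os.path.join(cfg.traces_dir, f"{rec.sample_id}.tsv")
        traces[rec.sample_id] = read_trace(
            path,
            geometry,
            displacement_unit=cfg.displacement_unit,
            force_unit=cfg.force_unit,
            sample_id=rec.sample_id,
        )
    log.info("[ingest] %d records, %d traces", len(records), len(traces))
    return records, traces


@_stage("mechanics")
def _mechanics(cfg: RunConfig, records, traces) -> pd.DataFrame:
    derived = derive_quantities(records, traces, cfg.slope, cfg.qc_threshold_pa)
    n_drop = int((~derived["qc_pass"]).sum())
    if n_drop:
        log.warning("[mechanics] QC dropped %d of %d samples", n_drop, len(derived))
    return derived


@_stage("stats")
def analyze_records(
    records: Sequence[SampleRecord],
    schemes: Sequence[str] = SCHEME_NAMES,
) -> dict:
    """Fit both responses for each requested scheme on QC-passed records.

    Returns {"schemes": ..., "anova": DataFrame, "contrasts": DataFrame,
    "percent": DataFrame, "results": {(scheme, response): MixedModelResult}}.
    """
    retained = [r for r in records if r.qc_pass]
    if not retained:
        raise PipelineError("[stats] empty analysis set (all samples dropped by QC)")
    scheme_objs = [assign_scheme(retained, s) for s in schemes]
    anova_rows, contrast_rows, pct_rows = [], [], []
    results: dict[tuple[str, str], MixedModelResult] = {}
    for scheme in scheme_objs:
        for response in ("log_EI", "log_E"):
            spec = ModelSpec(response=response, scheme=scheme.name)
            frame = build_analysis_frame(retained, scheme)
            res = fit_group_model(frame, spec)
            if res.singular:
                log.warning(
                    "[stats] singular fit for %s/%s (plant variance at zero)",
                    scheme.name,
                    response,
                )
            results[(scheme.name, response)] = res
            for _, row in res.f_table.iterrows():
                anova_rows.append(
                    {"scheme": scheme.name, "response": response, **row.to_dict()}
                )
            for (a, b), c in res.contrasts.items():
                contrast_rows.append(
                    {
                        "scheme": scheme.name,
                        "response": response,
                        "pair": f"{a} - {b}",
                        "estimate": c["estimate"],
                        "se": c["se"],
                        "t": c["t"],
                        "df": c["df"],
                        "p_adj": c["p_adjusted"],
                    }
                )
            if response == "log_EI":
                for a, b in [
                    (x, y)
                    for i, x in enumerate(res.levels)
                    for y in res.levels[i + 1 :]
                ]:
                    pct_rows.append(
                        {
                            "scheme": scheme.name,
                            "reference": a,
                            "level": b,
                            "pct_median": percent_rigidity_difference(frame, a, b, "median"),
                            "pct_emm": percent_rigidity_difference(res, a, b, "emm"),
                        }
                    )
    return {
        "schemes": scheme_objs,
        "anova": pd.DataFrame(anova_rows),
        "contrasts": pd.DataFrame(contrast_rows),
        "percent": pd.DataFrame(pct_rows),
        "results": results,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run ingest -> mechanics -> QC -> schemes -> models and write artifacts.

    Outputs (all delimited text under ``cfg.out_dir``): derived.csv,
    schemes.csv, anova.csv, contrasts.csv, percent_differences.csv and
    run_log.json (versions, seed, QC accounting).
    """
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    os.makedirs(cfg.out_dir, exist_ok=True)
    records, traces = _load(cfg)
    derived = _mechanics(cfg, records, traces)
    retained, dropped = qc_filter(records, cfg.qc_threshold_pa)
    if not retained:
        raise PipelineError("[qc] empty analysis set: every sample exceeded the QC threshold")
    analysis = analyze_records(records, cfg.schemes)

    derived.to_csv(os.path.join(cfg.out_dir, "derived.csv"), index=False)
    schemes_long_table(analysis["schemes"]).to_csv(
        os.path.join(cfg.out_dir, "schemes.csv"), index=False
    )
    analysis["anova"].to_csv(os.path.join(cfg.out_dir, "anova.csv"), index=False)
    analysis["contrasts"].to_csv(os.path.join(cfg.out_dir, "contrasts.csv"), index=False)
    analysis["percent"].to_csv(
        os.path.join(cfg.out_dir, "percent_differences.csv"), index=False
    )
    run_log = {
        "probemech_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "n_input": len(records),
        "n_retained": len(retained),
        "n_qc_dropped": len(dropped),
        "qc_threshold_pa": cfg.qc_threshold_pa,
        "geometry": {"span_L": cfg.span_L, "offset_a": cfg.offset_a},
        "schemes": list(cfg.schemes),
        "singular_fits": [
            f"{k[0]}/{k[1]}" for k, v in analysis["results"].items() if v.singular
        ],
    }
    with open(os.path.join(cfg.out_dir, "run_log.json"), "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    log.info(
        "[report] wrote artifacts to %s (input=%d retained=%d dropped=%d)",
        cfg.out_dir,
        len(records),
        len(retained),
        len(dropped),
    )
    return {"derived": derived, "run_log": run_log, **analysis}
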