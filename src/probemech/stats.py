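"""Group comparisons: mixed models on log responses, type-II F tests,
Tukey-adjusted EMM contrasts and back-transformed percent differences.

The modelled responses are log flexural rigidity (with log second moment of
area as a continuous covariate, controlling for tool geometry) or log elastic
modulus (no geometric covariate: E is already geometry-normalised). Every
model carries a per-plant random intercept because multiple samples come from
each individual plant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .groups import GroupScheme
from .ingest import SampleRecord
from .lmm import FTest, LMMError, RandomInterceptLMM

__all__ = [
    "ModelSpec",
    "MixedModelResult",
    "StatsError",
    "build_analysis_frame",
    "fit_group_model",
    "anova_type2",
    "emm_contrasts",
    "percent_rigidity_difference",
]

RESPONSES = ("log_EI", "log_E")


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Which response is modelled against which grouping scheme.

    ``log_I`` enters as a fixed covariate if and only if the response is
    ``log_EI``; elastic modulus is a material property and needs no geometric
    control.
    """

    response: str
    scheme: str

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise StatsError(f"response must be one of {RESPONSES}, got {self.response!r}")

    @property
    def with_log_I(self) -> bool:
        return self.response == "log_EI"


@dataclass
class MixedModelResult:
    """Fitted model plus everything the downstream report needs."""

    spec: ModelSpec
    levels: tuple[str, ...]
    model: RandomInterceptLMM
    fixed_effects: dict[str, tuple[float, float]]  # label -> (estimate, se) log scale
    var_components: dict[str, float]  # plant_var, residual_var
    log_I_mean: float | None
    singular: bool
    f_table: pd.DataFrame | None = None
    emms: dict[str, tuple[float, float]] = field(default_factory=dict)
    contrasts: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


def build_analysis_frame(
    records: Iterable[SampleRecord], scheme: GroupScheme
) -> pd.DataFrame:
    """Per-sample analysis table for one scheme: level, plant, EI, E, I.

    Only QC-passed records in the scheme's subset are included.
    """
    rows = []
    for r in records:
        if r.sample_id not in scheme.assignment:
            continue
        if r.qc_pass is False:
            continue
        if r.EI is None or r.E is None:
            raise StatsError(f"{r.sample_id}: derived quantities missing; run mechanics first")
        rows.append(
            {
                "sample_id": r.sample_id,
                "plant_id": r.plant_id,
                "level": scheme.assignment[r.sample_id],
                "EI_Nm2": r.EI,
                "E_Pa": r.E,
                "I_m4": r.section.second_moment(),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["sample_id", "plant_id", "level", "EI_Nm2", "E_Pa", "I_m4"]
    )
    frame.attrs["level_order"] = list(scheme.levels)
    return frame


def _design(frame: pd.DataFrame, levels: Sequence[str], with_log_I: bool):
    """Treatment-coded design: intercept, level dummies (first level reference),
    optionally centred-at-nothing log I. Returns (X, names)."""
    n = len(frame)
    cols = [np.ones(n)]
    names = ["(intercept)"]
    for lv in levels[1:]:
        cols.append((frame["level"] == lv).to_numpy(dtype=float))
        names.append(f"level[{lv}]")
    if with_log_I:
        cols.append(np.log(frame["I_m4"].to_numpy()))
        names.append("log_I")
    return np.column_stack(cols), names


def fit_group_model(frame: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """REML fit of log(response) ~ level (+ log I) with per-plant random intercept.

    ``frame`` is the output of :func:`build_analysis_frame`. Singular fits
    (plant variance at zero) are flagged, not fatal.
    """
    if frame.empty:
        raise StatsError("empty analysis set")
    present = [lv for lv in frame["level"].unique()]
    if len(present) < 2:
        raise StatsError(f"scheme has a single level ({present}); nothing to compare")
    # declared order for presentation; the design itself always uses the
    # sorted order so relabelling cannot perturb the numerical fit
    levels = tuple(lv for lv in _level_order(frame, spec) if lv in present)
    canon = tuple(sorted(present))

    resp_col = "EI_Nm2" if spec.response == "log_EI" else "E_Pa"
    vals = frame[resp_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise StatsError(f"non-positive {resp_col} values cannot be log-transformed")
    y = np.log(vals)
    X, names = _design(frame, canon, spec.with_log_I)
    model = RandomInterceptLMM(y, X, frame["plant_id"].to_numpy(), exog_names=names).fit()

    fixed = {
        nm: (float(b), float(math.sqrt(v)))
        for nm, b, v in zip(names, model.beta, np.diag(model.cov_beta))
    }
    log_I_mean = float(np.mean(np.log(frame["I_m4"]))) if spec.with_log_I else None
    result = MixedModelResult(
        spec=spec,
        levels=levels,
        model=model,
        fixed_effects=fixed,
        var_components={"plant_var": model.tau2, "residual_var": model.sigma2},
        log_I_mean=log_I_mean,
        singular=model.singular,
    )
    result.f_table = anova_type2(result)
    result.emms, result.contrasts = emm_contrasts(result)
    return result


def _level_order(frame: pd.DataFrame, spec: ModelSpec) -> tuple[str, ...]:
    # order of first appearance unless the caller attached explicit ordering
    order = frame.attrs.get("level_order")
    if order:
        return tuple(order)
    seen: list[str] = []
    for lv in frame["level"]:
        if lv not in seen:
            seen.append(lv)
    return tuple(seen)


def anova_type2(result: MixedModelResult) -> pd.DataFrame:
    """Type-II F table (term, F, df_num, df_den, p) with Satterthwaite df.

    With no interaction terms in the model, the type-II test for each term is
    the Wald test of that term's coefficients adjusted for all others.
    """
    model = result.model
    if not model.fitted:
        raise StatsError("model is not fitted")
    rows = []
    names = model.exog_names
    term_cols: dict[str, list[int]] = {}
    for j, nm in enumerate(names):
        if nm.startswith("level["):
            term_cols.setdefault("level", []).append(j)
        elif nm == "log_I":
            term_cols.setdefault("log_I", []).append(j)
    for term, cols in term_cols.items():
        L = np.zeros((len(cols), len(names)))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        ft = model.f_test(L)
        rows.append(
            {
                "term": result.spec.scheme if term == "level" else term,
                "F": ft.fvalue,
                "df_num": ft.df_num,
                "df_den": ft.df_den,
                "p": ft.pvalue,
            }
        )
    return pd.DataFrame(rows)


def emm_contrasts(
    result: MixedModelResult, adjust: str = "tukey"
) -> tuple[dict[str, tuple[float, float]], dict[tuple[str, str], dict[str, float]]]:
    """Estimated marginal means and all pairwise Tukey-adjusted contrasts.

    EMMs are evaluated at the grand mean of log I (when the covariate is in
    the model). Contrast (a, b) is EMM_a - EMM_b for a preceding b in the
    declared level order; the family-wise adjustment uses the studentized
    range over the number of levels.
    """
    model = result.model
    if not model.fitted:
        raise StatsError("model is not fitted")
    if adjust not in ("tukey", "none"):
        raise StatsError(f"unknown adjustment {adjust!r}")
    levels = result.levels
    if len(levels) < 2:
        raise StatsError("need at least two levels for contrasts")
    names = model.exog_names
    k = len(levels)

    def emm_row(lv: str) -> np.ndarray:
        x = np.zeros(len(names))
        x[names.index("(intercept)")] = 1.0
        key = f"level[{lv}]"
        if key in names:
            x[names.index(key)] = 1.0
        if "log_I" in names:
            x[names.index("log_I")] = result.log_I_mean
        return x

    emms: dict[str, tuple[float, float]] = {}
    for lv in levels:
        x = emm_row(lv)
        est = float(x @ model.beta)
        se = math.sqrt(float(x @ model.cov_beta @ x))
        emms[lv] = (est, se)

    contrasts: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in itertools.combinations(levels, 2):
        ell = emm_row(a) - emm_row(b)
        _, se, _, df = model.t_test(ell)
        # estimate as the literal EMM difference => exact antisymmetry
        est = emms[a][0] - emms[b][0]
        t = est / se if se > 0 else math.nan
        p_unadj = 2.0 * float(sps.t.sf(abs(t), df))
        if adjust == "tukey" and k > 2:
            p_adj = float(sps.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
        else:
            p_adj = p_unadj
        contrasts[(a, b)] = {
            "estimate": est,
            "se": se,
            "t": t,
            "df": df,
            "p_unadjusted": p_unadj,
            "p_adjusted": min(max(p_adj, p_unadj), 1.0),
        }
    return emms, contrasts


def percent_rigidity_difference(
    source,
    level_a: str,
    level_b: str,
    basis: str = "median",
) -> float:
    """Percent by which level_b is more (+) or less (-) rigid than level_a.

    basis="median" uses raw group medians of EI from an analysis frame;
    basis="emm" back-transforms the difference of estimated marginal means of
    a fitted log-EI model: (exp(EMM_b - EMM_a) - 1) * 100.
    """
    if basis == "median":
        if not isinstance(source, pd.DataFrame):
            raise StatsError("median basis requires an analysis frame")
        med = source.groupby("level")["EI_Nm2"].median()
        for lv in (level_a, level_b):
            if lv not in med.index:
                raise StatsError(f"level {lv!r} not present")
        if med[level_a] == 0:
            raise StatsError("zero median in reference level")
        return (med[level_b] / med[level_a] - 1.0) * 100.0
    if basis == "emm":
        if not isinstance(source, MixedModelResult):
            raise StatsError("emm basis requires a fitted MixedModelResult")
        for lv in (level_a, level_b):
            if lv not in source.emms:
                raise StatsError(f"level {lv!r} not present")
        diff = source.emms[level_b][0] - source.emms[level_a][0]
        return (math.exp(diff) - 1.0) * 100.0
    raise StatsError(f"unknown basis {basis!r}")
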