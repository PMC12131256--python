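"""Synthetic bending studies with known ground truth.

Generates a species -> plant -> sample hierarchy with log-normal per-material
elastic moduli (species, plant and residual log-scale variance components),
draws cross-sections per material at probe-tool dimensions, and renders each
sample as a raw force-displacement trace whose initial slope encodes the
sample's true flexural rigidity:

    slope = 48 EI / (a (3 L^2 - 4 a^2))

Traces get an optional quadratic toe region and additive Gaussian force
noise. Everything is deterministic under a fixed seed, with per-sample
substreams so traces can be regenerated independently.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ingest import (
    MATERIAL_TYPES,
    PREFERENCE_LEVELS,
    BendingTrace,
    CrossSection,
    Geometry,
    SampleRecord,
)

__all__ = [
    "SyntheticConfig",
    "SampleTruth",
    "GroundTruth",
    "SynthError",
    "generate_cohort",
    "simulate_trace",
    "write_cohort",
]


class SynthError(ValueError):
    pass


_DEFAULT_LOG_E = {
    # log Pa; woody materials sit in the few-GPa band, bark well below
    "twig": math.log(5e9),
    "vine": math.log(3e9),
    "grass": math.log(4e9),
    "bark": math.log(0.8e9),
}

_DEFAULT_DIMENSIONS = {
    # material -> dict of dimension ranges in metres (probe-tool scale)
    "twig": {"radius": (0.0008, 0.003)},
    "vine": {"radius": (0.0008, 0.003)},
    "grass": {"radius": (0.0005, 0.0015)},
    "bark": {"width": (0.002, 0.008), "depth": (0.0008, 0.002)},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to generate one synthetic study."""

    seed: int = 0
    # number of species per preference category; never_used species are the
    # non-tool-source pool
    n_species: Mapping[str, int] = field(
        default_factory=lambda: {"most_preferred": 2, "less_preferred": 4, "never_used": 3}
    )
    plants_per_species: int = 5
    samples_per_plant: int = 3
    material_mix: Mapping[str, float] = field(
        default_factory=lambda: {"twig": 0.6, "vine": 0.1, "bark": 0.25, "grass": 0.05}
    )
    logE_means: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOG_E))
    species_sd: float = 0.45
    plant_sd: float = 0.35
    residual_sd: float = 0.25
    effect_logEI: Mapping[str, float] = field(
        default_factory=lambda: {lv: 0.0 for lv in PREFERENCE_LEVELS}
    )
    span_L: float = 0.1  # arbitrary plausible portable-rig scale
    offset_a: float = 0.025
    dimension_ranges: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_DIMENSIONS.items()}
    )
    n_trace_points: int = 100
    max_displacement: float = 0.005
    noise_sd: float = 0.0  # newtons
    toe_fraction: float = 0.0
    used_probability: float = 0.35  # P(plant bears removal scars | tool source)
    n_mounds: int = 9

    def __post_init__(self) -> None:
        for lv in self.n_species:
            if lv not in PREFERENCE_LEVELS:
                raise SynthError(f"unknown preference category {lv!r}")
        if self.plants_per_species < 1:
            raise SynthError("need at least one plant per species")
        if self.samples_per_plant < 1:
            raise SynthError("need at least one sample per plant")
        mix = dict(self.material_mix)
        if any(m not in MATERIAL_TYPES for m in mix):
            raise SynthError(f"material_mix keys must be among {MATERIAL_TYPES}")
        if any(p < 0 for p in mix.values()) or not math.isclose(
            sum(mix.values()), 1.0, rel_tol=0, abs_tol=1e-9
        ):
            raise SynthError("material_mix proportions must be >= 0 and sum to 1")
        for sd in (self.species_sd, self.plant_sd, self.residual_sd, self.noise_sd):
            if sd < 0:
                raise SynthError("standard deviations must be >= 0")
        if not 0 <= self.toe_fraction < 1:
            raise SynthError("toe_fraction must be in [0, 1)")
        Geometry(self.span_L, self.offset_a)
        for mat, dims in self.dimension_ranges.items():
            for name, (lo, hi) in dims.items():
                if not (0 < lo <= hi):
                    raise SynthError(f"bad dimension range for {mat}.{name}: ({lo}, {hi})")

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.span_L, self.offset_a)


@dataclass(frozen=True)
class SampleTruth:
    E_true: float
    I_true: float
    EI_true: float
    slope_true: float
    trace_seed: int


GroundTruth = dict[str, SampleTruth]


def _slope_for(EI: float, L: float, a: float) -> float:
    return 48.0 * EI / (a * (3 * L**2 - 4 * a**2))


def _draw_section(material: str, cfg: SyntheticConfig, rng: np.random.Generator) -> CrossSection:
    dims = cfg.dimension_ranges[material]
    if "radius" in dims:
        lo, hi = dims["radius"]
        return CrossSection(shape="circular", radius=float(rng.uniform(lo, hi)))
    wlo, whi = dims["width"]
    dlo, dhi = dims["depth"]
    return CrossSection(
        shape="rectangular",
        width=float(rng.uniform(wlo, whi)),
        depth=float(rng.uniform(dlo, dhi)),
    )


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[SampleRecord], GroundTruth]:
    """Build the sample hierarchy and per-sample mechanical ground truth.

    Per-sample log E = material mean + preference offset + species effect +
    plant effect + residual; EI_true = E_true * I(section). Deterministic
    under ``cfg.seed``.
    """
    if not any(n > 0 for n in cfg.n_species.values()):
        raise SynthError("at least one species is required")
    rng = np.random.default_rng(cfg.seed)
    # independent substream seeds for each trace, drawn up front for stability
    records: list[SampleRecord] = []
    truth: GroundTruth = {}
    materials = list(cfg.material_mix)
    probs = np.array([cfg.material_mix[m] for m in materials], dtype=float)

    species_counter = 0
    plant_counter = 0
    sample_counter = 0
    for pref in PREFERENCE_LEVELS:
        for _ in range(int(cfg.n_species.get(pref, 0))):
            species_counter += 1
            species_id = f"SP{species_counter:03d}"
            species_eff = rng.normal(0.0, cfg.species_sd)
            tool_source = pref != "never_used"
            for _ in range(cfg.plants_per_species):
                plant_counter += 1
                plant_id = f"PL{plant_counter:04d}"
                plant_eff = rng.normal(0.0, cfg.plant_sd)
                mound = f"GTM{1 + (plant_counter - 1) % cfg.n_mounds:03d}"
                used = bool(tool_source and rng.random() < cfg.used_probability)
                for _ in range(cfg.samples_per_plant):
                    sample_counter += 1
                    sid = f"S{sample_counter:05d}"
                    material = materials[int(rng.choice(len(materials), p=probs))]
                    section = _draw_section(material, cfg, rng)
                    log_e = (
                        cfg.logE_means[material]
                        + cfg.effect_logEI.get(pref, 0.0)
                        + species_eff
                        + plant_eff
                        + rng.normal(0.0, cfg.residual_sd)
                    )
                    E = float(np.exp(log_e))
                    I = section.second_moment()
                    EI = E * I
                    truth[sid] = SampleTruth(
                        E_true=E,
                        I_true=I,
                        EI_true=EI,
                        slope_true=_slope_for(EI, cfg.span_L, cfg.offset_a),
                        trace_seed=int(rng.integers(0, 2**63 - 1)),
                    )
                    records.append(
                        SampleRecord(
                            sample_id=sid,
                            plant_id=plant_id,
                            species=species_id,
                            mound_id=mound,
                            plant_part="stem" if material in ("twig", "bark") else "branch",
                            material_type=material,
                            section=section,
                            length=float(rng.uniform(0.1, 0.5)),
                            tool_source_species=tool_source,
                            preference=pref,
                            plant_used=used,
                        )
                    )
    return records, truth


def simulate_trace(
    sample_id: str, truth: SampleTruth, cfg: SyntheticConfig
) -> BendingTrace:
    """Render one sample's force-displacement trace from its true slope.

    The displacement grid spans [0, max_displacement]. Beyond the toe the
    force is slope * (x - x_toe / 2); inside the toe it rises quadratically
    (C1-continuous at the junction). Gaussian force noise is added when
    configured. Uses the sample's private substream, so regeneration order
    does not matter.
    """
    if not truth.slope_true > 0:
        raise SynthError(f"{sample_id}: non-positive true slope")
    rng = np.random.default_rng(truth.trace_seed)
    x = np.linspace(0.0, cfg.max_displacement, cfg.n_trace_points)
    x_toe = cfg.toe_fraction * cfg.max_displacement
    if x_toe > 0:
        force = np.where(
            x < x_toe,
            truth.slope_true * x**2 / (2.0 * x_toe),
            truth.slope_true * (x - x_toe / 2.0),
        )
    else:
        force = truth.slope_true * x
    if cfg.noise_sd > 0:
        force = force + rng.normal(0.0, cfg.noise_sd, size=len(x))
    return BendingTrace(
        sample_id=sample_id,
        displacement=x,
        force=force,
        span_L=cfg.span_L,
        offset_a=cfg.offset_a,
    )


def write_cohort(
    records: list[SampleRecord],
    truth: GroundTruth,
    cfg: SyntheticConfig,
    outdir: str | os.PathLike,
) -> None:
    """Write the cohort in exactly the formats the ingest module reads.

    Layout: <outdir>/metadata.csv, <outdir>/traces/<sample_id>.csv and
    <outdir>/ground_truth.csv (sample_id, E_true, I_true, EI_true, slope_true).
    """
    from .ingest import write_records

    outdir = os.fspath(outdir)
    traces_dir = os.path.join(outdir, "traces")
    os.makedirs(traces_dir, exist_ok=True)
    write_records(records, os.path.join(outdir, "metadata.csv"))
    for rec in records:
        tr = simulate_trace(rec.sample_id, truth[rec.sample_id], cfg)
        pd.DataFrame({"displacement_m": tr.displacement, "force_N": tr.force}).to_csv(
            os.path.join(traces_dir, f"{rec.sample_id}.csv"),
            index=False,
            float_format="%.17g",
        )
    gt = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "E_true": t.E_true,
                "I_true": t.I_true,
                "EI_true": t.EI_true,
                "slope_true": t.slope_true,
            }
            for sid, t in truth.items()
        ]
    )
    gt.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False, float_format="%.17g")
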