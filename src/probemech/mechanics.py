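"""Beam mechanics: initial slope, flexural rigidity, second moments, modulus, QC.

The load case is four-point bending: a beam on two lower supports a span ``L``
apart, loaded by two inner probes each offset ``a`` from the nearer support.
The initial slope dF/dx of the force-displacement curve gives the flexural
rigidity

    EI = (dF/dx) * a * (3 L^2 - 4 a^2) / 48

and dividing by the cross-section's second moment of area I yields the
elastic modulus E. Samples whose E comes out implausibly high (> 35 GPa,
strictly) are flagged as QC failures and excluded from analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import BendingTrace, SampleRecord

__all__ = [
    "SlopeConfig",
    "SlopeEstimate",
    "MechanicsError",
    "QC_THRESHOLD_PA",
    "extract_initial_slope",
    "flexural_rigidity",
    "second_moment_circular",
    "second_moment_rectangular",
    "elastic_modulus",
    "qc_filter",
    "derive_quantities",
]

QC_THRESHOLD_PA = 35e9


class MechanicsError(ValueError):
    """Trace unsuitable for slope extraction or invalid mechanical input."""


@dataclass(frozen=True)
class SlopeConfig:
    """Controls for initial-slope extraction.

    min_points
        Smallest admissible fit window.
    search_fraction
        Fraction of the displacement range (from the start) searched for the
        initial linear region.
    r2_threshold
        Minimum coefficient of determination for an accepted window.
    toe_force_fraction
        Leading points with force below this fraction of the peak force are
        treated as toe/seating artefacts and discarded.
    toe_slope_fraction
        After the force floor, leading points whose local slope is below this
        fraction of the typical early-region slope are also trimmed; this
        catches the curved tail of a toe that already clears the force floor.
    """

    min_points: int = 5
    search_fraction: float = 0.5
    r2_threshold: float = 0.99
    toe_force_fraction: float = 0.02
    toe_slope_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.min_points < 3:
            raise MechanicsError("min_points must be >= 3")
        if not 0 < self.search_fraction <= 1:
            raise MechanicsError("search_fraction must be in (0, 1]")
        if not 0 < self.r2_threshold <= 1:
            raise MechanicsError("r2_threshold must be in (0, 1]")
        if not 0 <= self.toe_force_fraction < 1:
            raise MechanicsError("toe_force_fraction must be in [0, 1)")
        if not 0 <= self.toe_slope_fraction < 1:
            raise MechanicsError("toe_slope_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SlopeEstimate:
    """Least-squares initial slope with its fit window and diagnostics."""

    slope: float
    window_start_idx: int
    window_end_idx: int  # inclusive, indices into the original trace
    fit_r2: float

    @property
    def n_points(self) -> int:
        return self.window_end_idx - self.window_start_idx + 1


def _window_stats(x: np.ndarray, y: np.ndarray):
    """Prefix sums enabling O(1) slope/r2 for any contiguous window."""
    z = np.zeros(1)
    cx = np.concatenate([z, np.cumsum(x)])
    cy = np.concatenate([z, np.cumsum(y)])
    cxx = np.concatenate([z, np.cumsum(x * x)])
    cxy = np.concatenate([z, np.cumsum(x * y)])
    cyy = np.concatenate([z, np.cumsum(y * y)])

    def stats(i: int, j: int) -> tuple[float, float]:
        """Slope and r^2 of the OLS line over points i..j inclusive."""
        n = j - i + 1
        sx = cx[j + 1] - cx[i]
        sy = cy[j + 1] - cy[i]
        sxx = cxx[j + 1] - cxx[i]
        sxy = cxy[j + 1] - cxy[i]
        syy = cyy[j + 1] - cyy[i]
        ssx = sxx - sx * sx / n
        ssy = syy - sy * sy / n
        sxy_c = sxy - sx * sy / n
        if ssx <= 0:
            return math.nan, 0.0
        slope = sxy_c / ssx
        if ssy <= 0:
            return slope, 0.0
        r2 = (sxy_c * sxy_c) / (ssx * ssy)
        # guard tiny negative/overshoot from cancellation
        return slope, min(max(r2, 0.0), 1.0)

    return stats


def extract_initial_slope(trace: BendingTrace, cfg: SlopeConfig | None = None) -> SlopeEstimate:
    """Initial slope of a force-displacement curve, after toe exclusion.

    The toe region (seating/compliance) is removed in two passes: leading
    points below the force floor, then leading points whose local slope is
    well below the early-region's typical slope. Within the first
    ``search_fraction`` of the displacement range the longest window (ties:
    earliest) of at least ``min_points`` points achieving
    ``r2 >= r2_threshold`` is fit by ordinary least squares.
    """
    cfg = cfg or SlopeConfig()
    x = trace.displacement
    y = trace.force
    n = len(x)
    if n < cfg.min_points:
        raise MechanicsError(
            f"{trace.sample_id}: insufficient points ({n} < min_points={cfg.min_points})"
        )
    fmax = float(np.max(np.abs(y)))
    if fmax <= 0:
        raise MechanicsError(f"{trace.sample_id}: degenerate trace (all-zero force)")

    # pass 1: force floor
    floor = cfg.toe_force_fraction * fmax
    start = 0
    while start < n and y[start] < floor:
        start += 1

    # search region: first fraction of the displacement range
    x_lo, x_hi = x[0], x[-1]
    limit = x_lo + cfg.search_fraction * (x_hi - x_lo)
    end = int(np.searchsorted(x, limit, side="right")) - 1
    if end - start + 1 < cfg.min_points:
        end = min(n - 1, start + cfg.min_points - 1)
    if end - start + 1 < cfg.min_points:
        raise MechanicsError(f"{trace.sample_id}: search region too short for fit window")

    # pass 2: local-slope toe trim (centred differences over the region)
    if cfg.toe_slope_fraction > 0 and end - start + 1 >= cfg.min_points + 2:
        seg_x = x[start : end + 1]
        seg_y = y[start : end + 1]
        h = max(1, cfg.min_points // 2)
        m = len(seg_x)
        idx = np.arange(m)
        lo = np.maximum(idx - h, 0)
        hi = np.minimum(idx + h, m - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            local = (seg_y[hi] - seg_y[lo]) / (seg_x[hi] - seg_x[lo])
        ref = float(np.median(local[np.isfinite(local)]))
        if ref > 0:
            trim = 0
            while (
                trim < m - cfg.min_points
                and np.isfinite(local[trim])
                and local[trim] < cfg.toe_slope_fraction * ref
            ):
                trim += 1
            start += trim

    if end - start + 1 < cfg.min_points:
        raise MechanicsError(f"{trace.sample_id}: toe exclusion left too few points")

    stats = _window_stats(x[start : end + 1], y[start : end + 1])
    m = end - start + 1
    best: tuple[int, int] | None = None  # (length, -start) maximised
    best_ij: tuple[int, int] | None = None
    for i in range(0, m - cfg.min_points + 1):
        # longest admissible window from this start
        for j in range(m - 1, i + cfg.min_points - 2, -1):
            slope, r2 = stats(i, j)
            if r2 >= cfg.r2_threshold:
                key = (j - i, -i)
                if best is None or key > best:
                    best = key
                    best_ij = (i, j)
                break  # j descends, so the first passing window is the longest from this start
    if best_ij is None:
        raise MechanicsError(
            f"{trace.sample_id}: no window of >= {cfg.min_points} points reaches "
            f"r2 >= {cfg.r2_threshold}"
        )
    i, j = best_ij
    slope, r2 = stats(i, j)
    if not math.isfinite(slope):
        raise MechanicsError(f"{trace.sample_id}: degenerate trace (zero displacement spread)")
    if slope < 0:
        raise MechanicsError(f"{trace.sample_id}: negative initial slope (corrupted trace)")
    if slope == 0:
        raise MechanicsError(f"{trace.sample_id}: degenerate trace (flat force)")
    return SlopeEstimate(
        slope=float(slope),
        window_start_idx=start + i,
        window_end_idx=start + j,
        fit_r2=float(r2),
    )


def flexural_rigidity(slope: float, span_L: float, offset_a: float) -> float:
    """EI from the initial slope under four-point bending.

    EI = slope * a * (3 L^2 - 4 a^2) / 48. At a = L/2 this reduces to the
    central-loading closed form slope * L^3 / 48.
    """
    if not (span_L > 0 and math.isfinite(span_L)):
        raise MechanicsError(f"span_L must be positive, got {span_L}")
    if not (0 < offset_a <= span_L / 2):
        raise MechanicsError(f"offset_a must satisfy 0 < a <= L/2, got {offset_a}")
    if slope < 0 or not math.isfinite(slope):
        raise MechanicsError(f"slope must be finite and >= 0, got {slope}")
    return slope * offset_a * (3 * span_L**2 - 4 * offset_a**2) / 48.0


def second_moment_circular(radius: float) -> float:
    """I = pi R^4 / 4 for a circular section."""
    if not (radius > 0 and math.isfinite(radius)):
        raise MechanicsError(f"radius must be positive, got {radius}")
    return math.pi * radius**4 / 4.0


def second_moment_rectangular(width: float, depth: float) -> float:
    """I = W D^3 / 12; depth is measured along the bending direction."""
    if not (width > 0 and math.isfinite(width)):
        raise MechanicsError(f"width must be positive, got {width}")
    if not (depth > 0 and math.isfinite(depth)):
        raise MechanicsError(f"depth must be positive, got {depth}")
    return width * depth**3 / 12.0


def elastic_modulus(EI: float, I: float) -> float:
    """E = EI / I (Pa)."""
    if not (I > 0 and math.isfinite(I)):
        raise MechanicsError(f"second moment I must be positive, got {I}")
    if EI < 0 or not math.isfinite(EI):
        raise MechanicsError(f"EI must be finite and >= 0, got {EI}")
    return EI / I


def qc_filter(
    records: Iterable[SampleRecord], threshold_pa: float = QC_THRESHOLD_PA
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Partition records into (retained, dropped) by the modulus ceiling.

    A record with E strictly above the threshold is flagged ``qc_pass=False``
    and dropped; E equal to the threshold is retained. Records lacking E are
    an error.
    """
    if not threshold_pa > 0:
        raise MechanicsError("QC threshold must be positive")
    retained: list[SampleRecord] = []
    dropped: list[SampleRecord] = []
    for rec in records:
        if rec.E is None:
            raise MechanicsError(f"{rec.sample_id}: record lacks E; run the mechanics stage first")
        rec.qc_pass = not rec.E > threshold_pa
        (retained if rec.qc_pass else dropped).append(rec)
    return retained, dropped


def derive_quantities(
    records: Sequence[SampleRecord],
    traces: dict[str, BendingTrace],
    cfg: SlopeConfig | None = None,
    qc_threshold_pa: float = QC_THRESHOLD_PA,
) -> pd.DataFrame:
    """Run slope -> EI -> I -> E -> QC for every record; mutates records in place.

    Returns the per-sample derived-quantities table (the mechanics/stats
    contract): sample_id, slope, r2, I_m4, EI_Nm2, E_Pa, qc_pass.
    """
    cfg = cfg or SlopeConfig()
    rows = []
    for rec in records:
        if rec.sample_id not in traces:
            raise MechanicsError(f"{rec.sample_id}: no trace supplied")
        trace = traces[rec.sample_id]
        est = extract_initial_slope(trace, cfg)
        EI = flexural_rigidity(est.slope, trace.span_L, trace.offset_a)
        I = rec.section.second_moment()  # always recomputed from canonical SI section
        E = elastic_modulus(EI, I)
        rec.EI = EI
        rec.E = E
        rec.qc_pass = not E > qc_threshold_pa
        rows.append(
            {
                "sample_id": rec.sample_id,
                "slope": est.slope,
                "r2": est.fit_r2,
                "I_m4": I,
                "EI_Nm2": EI,
                "E_Pa": E,
                "qc_pass": rec.qc_pass,
            }
        )
    return pd.DataFrame(rows)
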