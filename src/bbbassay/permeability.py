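"""Endothelial permeability coefficients and normalized TEER from raw
transwell data.

The chain per insert: per-interval cleared volume
``C_abluminal · V_abluminal / C_luminal`` is cumulated across the transfer
intervals, regressed on time (origin prepended, free intercept) to give the
total permeability-surface product PS_total; the cell-free filter
conductance is removed in series (``1/PS_e = 1/PS_t − 1/PS_f``) and PS_e is
divided by the insert area to give Pe on the 10⁻⁶ cm/s scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import AssayDesign, default_designs

__all__ = [
    "PermeabilityResult",
    "TeerResult",
    "PipelineError",
    "SeriesModelViolation",
    "compute_clearance",
    "fit_ps",
    "correct_for_insert",
    "compute_pe",
    "compute_teer",
    "run_permeability_pipeline",
    "compute_teer_table",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a plate cannot be analysed (e.g. no cell-free inserts)."""


class SeriesModelViolation(ValueError):
    """The monolayer appears more conductive than the bare filter — the
    series-conductance model is undefined; typically a symptom of noisy data."""


@dataclass
class PermeabilityResult:
    insert_id: str
    cleared_volumes_ul: tuple[float, ...]
    ps_total: float
    ps_insert: float
    ps_endothelial: float
    pe: float
    fit_r2: float


@dataclass
class TeerResult:
    teer: float
    raw_resistance: float
    area: float
    blank: float
    clipped: bool = False


def compute_clearance(
    abluminal_conc: float, abluminal_volume: float, luminal_conc: float
) -> float:
    """Cleared donor volume (µl): ``C_abluminal × V_abluminal / C_luminal``."""
    if luminal_conc <= 0:
        raise ValueError("luminal concentration must be positive")
    if abluminal_conc < 0 or abluminal_volume < 0:
        raise ValueError("abluminal concentration and volume must be non-negative")
    return abluminal_conc * abluminal_volume / luminal_conc


def fit_ps(
    times_min: Sequence[float], cumulative_cleared_ul: Sequence[float]
) -> tuple[float, float]:
    """OLS slope of cumulative cleared volume on time: the PS product (µl/min).

    The origin (0, 0) is prepended and an intercept is still estimated; only
    the slope is interpreted.  Returns ``(slope, r²)``.
    """
    t = np.concatenate([[0.0], np.asarray(times_min, dtype=float)])
    y = np.concatenate([[0.0], np.asarray(cumulative_cleared_ul, dtype=float)])
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("need >= 2 distinct time points to fit PS")
    res = stats.linregress(t, y)
    r2 = float(res.rvalue) ** 2 if not np.isnan(res.rvalue) else 1.0
    return float(res.slope), r2


def correct_for_insert(ps_total: float, ps_insert: float) -> float:
    """Remove the filter conductance in series: ``1/PS_e = 1/PS_t − 1/PS_f``."""
    if ps_total <= 0 or ps_insert <= 0:
        raise ValueError("PS values must be positive")
    if ps_total >= ps_insert:
        raise SeriesModelViolation(
            f"PS_total ({ps_total:g}) >= PS_insert ({ps_insert:g}): "
            "monolayer cannot be more conductive than the bare filter"
        )
    return 1.0 / (1.0 / ps_total - 1.0 / ps_insert)


def compute_pe(ps_endothelial: float, area_cm2: float) -> float:
    """Endothelial permeability coefficient on the 10⁻⁶ cm/s scale.

    Converts PS_e from µl/min to cm³/s (×10⁻³/60), divides by the insert
    area, and scales by 10⁶ for reporting.
    """
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    if ps_endothelial < 0:
        raise ValueError("ps_endothelial must be non-negative")
    return ps_endothelial * 1e-3 / 60.0 / area_cm2 * 1e6


def compute_teer(raw_resistance: float, area_cm2: float, blank: float = 70.0) -> TeerResult:
    """Area-normalized TEER with blank-filter subtraction.

    ``TEER = R_raw · A − blank`` (Ω·cm²); negative results are clipped to 0
    and flagged, as happens with leaky monolayers near the blank.
    """
    if raw_resistance < 0:
        raise ValueError("raw resistance must be non-negative")
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    teer = raw_resistance * area_cm2 - blank
    clipped = teer < 0
    if clipped:
        warnings.warn(
            f"TEER {teer:.1f} below blank; clipped to 0", stacklevel=2
        )
        teer = 0.0
    return TeerResult(teer=float(teer), raw_resistance=float(raw_resistance),
                      area=float(area_cm2), blank=float(blank), clipped=clipped)


def _insert_results(
    group: pd.DataFrame, design: AssayDesign
) -> tuple[tuple[float, ...], float, float]:
    """Cumulative cleared volumes, PS slope and r² for one insert's rows."""
    g = group.sort_values("interval_end_min")
    times = g["interval_end_min"].to_numpy(dtype=float)
    cleared = np.array(
        [
            compute_clearance(a, design.abluminal_volume_ul, l)
            for a, l in zip(g["abluminal_conc"], g["luminal_conc_nominal"])
        ]
    )
    cumulative = np.cumsum(cleared)
    slope, r2 = fit_ps(times, cumulative)
    return tuple(float(c) for c in cumulative), slope, r2


def run_permeability_pipeline(
    table: pd.DataFrame,
    designs: Mapping[str, AssayDesign] | None = None,
    ps_insert_override: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Estimate Pe for every cell-bearing insert of a long permeability table.

    Per tracer, PS_insert is the mean PS over that tracer's cell-free inserts
    (or the value in ``ps_insert_override``).  Rows violating the series
    model (PS_total ≥ PS_insert) are flagged ``excluded`` with NaN Pe and a
    logged warning rather than aborting the plate.

    Returns one row per cell-bearing insert: identifiers, the cumulative
    cleared volumes, PS_total / PS_insert / PS_endothelial (µl/min), Pe
    (10⁻⁶ cm/s) and the regression r².
    """
    designs = dict(designs) if designs is not None else default_designs()
    required = {"insert_id", "tracer", "cell_free", "interval_end_min",
                "abluminal_conc", "luminal_conc_nominal"}
    missing = required - set(table.columns)
    if missing:
        raise PipelineError(f"permeability table missing columns: {sorted(missing)}")

    cell_free = table[table["cell_free"].astype(bool)]
    cell_bearing = table[~table["cell_free"].astype(bool)]
    if cell_bearing.empty:
        raise PipelineError("plate contains only cell-free inserts")

    ps_insert: dict[str, float] = {}
    for tracer in cell_bearing["tracer"].unique():
        if ps_insert_override and tracer in ps_insert_override:
            ps_insert[tracer] = float(ps_insert_override[tracer])
            continue
        cf = cell_free[cell_free["tracer"] == tracer]
        if cf.empty:
            raise PipelineError(f"no cell-free insert for tracer {tracer!r}")
        slopes = [
            _insert_results(g, designs[tracer])[1]
            for _, g in cf.groupby("insert_id", sort=True)
        ]
        ps_insert[tracer] = float(np.mean(slopes))

    rows: list[dict] = []
    for (insert_id, tracer), g in cell_bearing.groupby(
        ["insert_id", "tracer"], sort=True
    ):
        design = designs[tracer]
        cumulative, ps_t, r2 = _insert_results(g, design)
        row = {
            "insert_id": insert_id,
            "tracer": tracer,
            "dose_gy": float(g["dose_gy"].iloc[0]) if "dose_gy" in g else np.nan,
            "day": int(g["day"].iloc[0]) if "day" in g else -1,
            "cleared_volumes_ul": cumulative,
            "ps_total": ps_t,
            "ps_insert": ps_insert[tracer],
            "fit_r2": r2,
            "excluded": False,
        }
        try:
            ps_e = correct_for_insert(ps_t, ps_insert[tracer])
            row["ps_endothelial"] = ps_e
            row["pe"] = compute_pe(ps_e, design.insert_area_cm2)
        except (SeriesModelViolation, ValueError) as err:
            logger.warning("insert %s excluded: %s", insert_id, err)
            row.update(ps_endothelial=np.nan, pe=np.nan, excluded=True)
        rows.append(row)
    return pd.DataFrame(rows)


def compute_teer_table(
    teer_table: pd.DataFrame, area_cm2: float = 0.33, blank: float = 70.0
) -> pd.DataFrame:
    """Apply :func:`compute_teer` to every raw resistance row of a long table."""
    if "raw_ohm" not in teer_table.columns:
        raise PipelineError("TEER table missing column 'raw_ohm'")
    out = teer_table.copy()
    results = [compute_teer(r, area_cm2, blank) for r in out["raw_ohm"]]
    out["teer"] = [r.teer for r in results]
    out["clipped"] = [r.clipped for r in results]
    return out
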