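"""Evans-blue tissue extravasation: plate calibration, ng/mg quantification,
and fold-changes versus sham.

The dye binds plasma albumin, so its tissue content reports albumin leakage
across a compromised blood-brain barrier.  Plate fluorescence is mapped to
dye concentration through a linear standard curve (classical calibration:
reading regressed on concentration, inverted for prediction), then scaled by
the formamide extract volume and tissue mass to ng dye per mg tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "TissueSample",
    "fit_standard_curve",
    "quantify_tissue",
    "quantify_invivo_table",
    "fold_change_vs_sham",
]


@dataclass
class CalibrationCurve:
    """Linear fluorescence↔concentration map with its fit diagnostics."""

    slope: float            # fluorescence units per (ng/ml)
    intercept: float        # fluorescence units
    r2: float
    standards: pd.DataFrame

    def concentration(self, reading: float) -> tuple[float, bool]:
        """Invert the curve; readings below the intercept clip to 0 (flagged)."""
        conc = (reading - self.intercept) / self.slope
        if conc < 0:
            return 0.0, True
        return conc, False


@dataclass
class TissueSample:
    animal_id: str
    dose_gy: float
    timepoint: str
    age_group: str
    region: str
    reading: float
    tissue_mass_mg: float
    extract_volume_ml: float = 0.5

    def __post_init__(self) -> None:
        if self.tissue_mass_mg <= 0:
            raise ValueError("tissue mass must be positive")
        if self.extract_volume_ml <= 0:
            raise ValueError("extract volume must be positive")


def fit_standard_curve(standards: pd.DataFrame) -> CalibrationCurve:
    """OLS line of plate reading on standard concentration (ng/ml).

    Expects columns ``conc_ng_ml`` and ``reading`` (a 7-point series in the
    study's design, but any >= 2 distinct concentrations fit).  Warns when
    r² < 0.98, the usual bench quality bar for a plate standard curve.
    """
    conc = np.asarray(standards["conc_ng_ml"], dtype=float)
    reading = np.asarray(standards["reading"], dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need >= 2 distinct standard concentrations")
    res = stats.linregress(conc, reading)
    if res.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    r2 = float(res.rvalue) ** 2
    if r2 < 0.98:
        warnings.warn(f"standard curve r² = {r2:.3f} < 0.98", stacklevel=2)
    return CalibrationCurve(
        slope=float(res.slope), intercept=float(res.intercept), r2=r2,
        standards=standards[["conc_ng_ml", "reading"]].copy(),
    )


def quantify_tissue(sample: TissueSample, curve: CalibrationCurve) -> float:
    """Tissue Evans-blue content in ng dye per mg tissue.

    ``content = concentration(reading) × extract_volume / tissue_mass``,
    with the concentration in ng/ml and the extract volume in ml.
    """
    conc, _clipped = curve.concentration(sample.reading)
    return conc * sample.extract_volume_ml / sample.tissue_mass_mg


def quantify_invivo_table(
    invivo: pd.DataFrame, curve: CalibrationCurve
) -> pd.DataFrame:
    """Vectorized :func:`quantify_tissue` over a long in-vivo table.

    Adds ``conc_ng_ml``, ``below_curve`` and ``evans_blue_ng_mg`` columns.
    """
    out = invivo.copy()
    conc = (out["reading"].astype(float) - curve.intercept) / curve.slope
    below = conc < 0
    conc = conc.clip(lower=0.0)
    out["conc_ng_ml"] = conc
    out["below_curve"] = below
    out["evans_blue_ng_mg"] = (
        conc * out["extract_volume_ml"].astype(float)
        / out["tissue_mass_mg"].astype(float)
    )
    return out


def fold_change_vs_sham(
    table: pd.DataFrame,
    value_col: str,
    stratify_by: tuple[str, ...] = ("age_group", "region", "timepoint"),
    dose_col: str = "dose_gy",
    sham_dose: float = 0.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratio of irradiated group mean to sham group mean within each stratum.

    A seeded nonparametric bootstrap (percentile method, ``n_boot``
    resamples of both groups) supplies a 95% interval for each ratio.
    """
    stratify_by = tuple(c for c in stratify_by if c in table.columns)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    grouped = table.groupby(list(stratify_by), sort=True) if stratify_by else [((), table)]
    for key, stratum in grouped:
        key = key if isinstance(key, tuple) else (key,)
        sham = stratum.loc[stratum[dose_col] == sham_dose, value_col].to_numpy(float)
        if sham.size == 0:
            raise ValueError(f"no sham group in stratum {dict(zip(stratify_by, key))}")
        for dose, g in stratum.groupby(dose_col, sort=True):
            if dose == sham_dose:
                continue
            vals = g[value_col].to_numpy(float)
            fold = vals.mean() / sham.mean()
            boots = np.empty(n_boot)
            for b in range(n_boot):
                num = rng.choice(vals, size=vals.size, replace=True).mean()
                den = rng.choice(sham, size=sham.size, replace=True).mean()
                boots[b] = num / den if den != 0 else np.nan
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            rows.append(
                dict(zip(stratify_by, key))
                | {
                    dose_col: float(dose),
                    "fold_change": float(fold),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n": int(vals.size),
                    "n_sham": int(sham.size),
                }
            )
    return pd.DataFrame(rows)
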