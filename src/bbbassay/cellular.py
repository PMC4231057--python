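"""Count-based cellular endpoints and immunofluorescence intensity.

Covers circulating endothelial progenitor (CEP) colony rates per 10⁵
peripheral blood mononuclear cells, SA-β-galactosidase-positive senescence
fractions with exact binomial intervals, cell densities per mm², and the
threshold/background-subtraction quantification of grayscale
immunofluorescence images.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

__all__ = [
    "cep_rate",
    "senescence_fraction",
    "cell_density",
    "quantify_intensity",
    "summarize_counts_table",
]


def cep_rate(colonies: int, pbmc: float) -> float:
    """Colony-forming units per 10⁵ peripheral blood mononuclear cells."""
    if pbmc <= 0:
        raise ValueError("PBMC count must be positive")
    if colonies < 0:
        raise ValueError("colony count must be non-negative")
    return colonies / pbmc * 1e5


def senescence_fraction(
    positive: int, total: int, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Percentage of SA-β-gal-positive cells with a Clopper–Pearson interval.

    Returns ``(percentage, (ci_low, ci_high))``, all on the 0–100 scale.
    The exact interval uses the beta-quantile form: lower
    ``B(α/2; x, n−x+1)``, upper ``B(1−α/2; x+1, n−x)``, with the usual
    degenerate endpoints at x = 0 and x = n.
    """
    if total < 1:
        raise ValueError("total count must be >= 1")
    if not 0 <= positive <= total:
        raise ValueError("positive count must be in [0, total]")
    pct = 100.0 * positive / total
    lo = 0.0 if positive == 0 else stats.beta.ppf(alpha / 2, positive, total - positive + 1)
    hi = 1.0 if positive == total else stats.beta.ppf(
        1 - alpha / 2, positive + 1, total - positive
    )
    return pct, (100.0 * float(lo), 100.0 * float(hi))


def cell_density(cells: int, field_area_mm2: float) -> float:
    """Cells per mm² of imaged field."""
    if field_area_mm2 <= 0:
        raise ValueError("field area must be positive")
    if cells < 0:
        raise ValueError("cell count must be non-negative")
    return cells / field_area_mm2


def quantify_intensity(pixels: np.ndarray, threshold: float | None = None) -> float:
    """Background-subtracted mean grayscale of the stained area of an image.

    The stained area is segmented by Otsu's threshold (override with
    ``threshold``); the background level is the mean of the sub-threshold
    ("non-expressing") pixels and is subtracted from every pixel (floored at
    0) before averaging the above-threshold pixels.  Invariant to adding a
    constant to the whole image.
    """
    img = np.asarray(pixels, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    if np.any(img < 0):
        raise ValueError("negative intensities are not meaningful")
    if np.ptp(img) == 0:
        raise ValueError("constant image: threshold is degenerate")
    thr = float(threshold) if threshold is not None else float(threshold_otsu(img))
    fg = img > thr
    bg = ~fg
    if not fg.any() or not bg.any():
        raise ValueError("threshold separates no foreground from background")
    background = float(img[bg].mean())
    corrected = np.clip(img - background, 0.0, None)
    return float(corrected[fg].mean())


def summarize_counts_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-row endpoint values for a long counts table.

    Maps each assay to its summary: ``cep`` → CFU per 10⁵ PBMC,
    ``senescence`` → percent positive, ``cell_density`` → cells/mm².
    Returns the table with an added ``value`` column (and ``endpoint`` label).
    """
    required = {"assay", "numerator", "denominator"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    out = counts.copy()
    values = np.empty(len(out))
    endpoints = []
    for i, (_, row) in enumerate(out.iterrows()):
        assay = row["assay"]
        num, den = int(row["numerator"]), float(row["denominator"])
        if assay == "cep":
            values[i] = cep_rate(num, den)
            endpoints.append("cep_cfu_per_1e5_pbmc")
        elif assay == "senescence":
            values[i] = senescence_fraction(num, int(den))[0]
            endpoints.append("senescence_pct")
        elif assay == "cell_density":
            values[i] = cell_density(num, den)
            endpoints.append("cells_per_mm2")
        else:
            raise ValueError(f"unknown assay {assay!r}")
    out["value"] = values
    out["endpoint"] = endpoints
    return out
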