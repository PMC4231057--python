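"""Forward simulation of the assays: transwell tracer transport with the
interval-transfer protocol, raw TEER readings, in-vivo Evans-blue tissue
levels with their plate calibration, and count-based cellular endpoints.

All generators require an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    AGE_GROUPS,
    DOSES_GY,
    INVITRO_DAYS,
    INVIVO_TIMEPOINTS,
    REGIONS,
    AssayDesign,
    EffectModel,
    TrueKinetics,
    default_designs,
    pe_to_ps,
)

__all__ = [
    "SimulatedStudy",
    "two_compartment_solution",
    "simulate_permeability_dataset",
    "simulate_in_vivo_dataset",
    "simulate_count_assays",
    "simulate_study",
]

#: default 7-point Evans-blue standard series, ng/ml
STANDARD_CONCENTRATIONS = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0)


@dataclass
class SimulatedStudy:
    """Bundle of simulated raw tables plus the provenance to regenerate them."""

    permeability_table: pd.DataFrame | None = None
    teer_table: pd.DataFrame | None = None
    invivo_table: pd.DataFrame | None = None
    standards_table: pd.DataFrame | None = None
    counts_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def two_compartment_solution(
    design: AssayDesign,
    ps_total: float,
    t: float,
    donor_start: float,
    receiver_start: float = 0.0,
) -> tuple[float, float]:
    """Exact concentrations after time ``t`` of conservative two-compartment
    exchange across a barrier of conductance ``ps_total`` (µl/min).

    The governing equations are
    ``dC_r/dt = (PS/V_r)(C_d - C_r)`` and ``dC_d/dt = -(PS/V_d)(C_d - C_r)``;
    the concentration difference decays as ``exp(-PS(1/V_d + 1/V_r) t)``
    around the common equilibrium set by total tracer mass.

    Returns ``(donor, receiver)`` concentrations in the donor's units.
    """
    if ps_total < 0:
        raise ValueError("ps_total must be non-negative")
    if t < 0:
        raise ValueError("time must be non-negative")
    if donor_start < 0 or receiver_start < 0:
        raise ValueError("concentrations must be non-negative")
    v_d = design.luminal_volume_ul
    v_r = design.abluminal_volume_ul
    mass = donor_start * v_d + receiver_start * v_r
    c_eq = mass / (v_d + v_r)
    diff = (donor_start - receiver_start) * math.exp(
        -ps_total * (1.0 / v_d + 1.0 / v_r) * t
    )
    donor = c_eq + diff * v_r / (v_d + v_r)
    receiver = c_eq - diff * v_d / (v_d + v_r)
    return donor, receiver


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _simulate_insert_intervals(
    design: AssayDesign, ps_total: float
) -> list[tuple[float, float, float]]:
    """Noise-free per-interval readings for one insert.

    At each sample time the insert is moved to a fresh receiver well: the
    receiver restarts at zero while the donor concentration carries over.
    Returns ``(interval_end_min, abluminal_conc, donor_at_interval_start)``.
    """
    rows = []
    donor = design.donor_concentration
    prev_t = 0.0
    for t_end in design.sample_times_min:
        donor_start = donor
        donor, receiver = two_compartment_solution(
            design, ps_total, t_end - prev_t, donor_start, receiver_start=0.0
        )
        rows.append((t_end, receiver, donor_start))
        prev_t = t_end
    return rows


def simulate_permeability_dataset(
    kinetics: TrueKinetics,
    *,
    n_inserts: int = 3,
    noise_cv: float = 0.10,
    seed: int,
    designs: Mapping[str, AssayDesign] | None = None,
    doses: Sequence[float] = DOSES_GY,
    days: Sequence[int] = INVITRO_DAYS,
    n_cell_free: int = 3,
    teer_noise_cv: float | None = None,
) -> SimulatedStudy:
    """Simulate the transwell permeability plate and its raw TEER readings.

    Each cell-bearing insert transports tracer through the endothelial layer
    and the coated filter in series (``1/PS_t = 1/PS_e + 1/PS_f``); cell-free
    inserts carry the filter conductance alone.  Measured abluminal
    concentrations receive mean-one multiplicative lognormal noise of
    coefficient of variation ``noise_cv``.  Raw resistance readings are
    ``(TEER_i + blank)/area`` with additive Gaussian measurement noise whose
    SD is ``teer_noise_cv`` (default: ``noise_cv``) times the group's layer
    resistance ``TEER/area`` (so a 10% noise CV gives 10% CV on recovered TEER); TEER_i itself is drawn around the group truth with the
    between-insert SD from ``kinetics``.
    """
    if seed is None:  # reproducibility contract
        raise ValueError("a seed is required for simulation")
    if n_inserts < 1:
        raise ValueError("n_inserts must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    designs = dict(designs) if designs is not None else default_designs()
    teer_noise_cv = noise_cv if teer_noise_cv is None else teer_noise_cv
    rng = np.random.default_rng(seed)

    perm_rows: list[dict] = []

    def emit(insert_id, dose, day, tracer, cell_free, design, ps_total):
        intervals = _simulate_insert_intervals(design, ps_total)
        noise = _lognormal_factors(rng, noise_cv, len(intervals))
        for (t_end, abl, _donor0), f in zip(intervals, noise):
            perm_rows.append(
                {
                    "insert_id": insert_id,
                    "dose_gy": dose,
                    "day": day,
                    "tracer": tracer,
                    "cell_free": cell_free,
                    "interval_end_min": t_end,
                    "abluminal_conc": abl * f,
                    "luminal_conc_nominal": design.donor_concentration,
                }
            )

    for tracer, design in designs.items():
        area = design.insert_area_cm2
        ps_f = pe_to_ps(kinetics.pe_insert[tracer], area)
        # cell-free coated membranes: one set per tracer per plate
        for k in range(n_cell_free):
            emit(f"CF-{tracer}-{k + 1}", 0.0, int(min(days)), tracer, True, design, ps_f)
        for dose in doses:
            for day in days:
                for k in range(n_inserts):
                    pe_e = kinetics.pe_true(tracer, dose, day)
                    ps_e = pe_to_ps(pe_e, area)
                    ps_t = 1.0 / (1.0 / ps_e + 1.0 / ps_f)
                    emit(
                        f"I-{tracer}-d{dose:g}-day{day}-{k + 1}",
                        float(dose),
                        int(day),
                        tracer,
                        False,
                        design,
                        ps_t,
                    )

    # raw TEER readings; area is a plate property, not tracer-specific
    area = next(iter(designs.values())).insert_area_cm2
    teer_rows: list[dict] = []
    for dose in doses:
        for day in days:
            teer_g = kinetics.teer_true(dose, day)
            truths = rng.normal(teer_g, kinetics.teer_between_sd, size=n_inserts)
            truths = np.clip(truths, 0.0, None)
            raw = (truths + kinetics.blank_teer) / area
            if teer_noise_cv > 0:
                # measurement noise sized to the layer's own resistance, so a
                # noise CV of 0.10 yields 10% CV on the recovered TEER
                raw = raw + rng.normal(
                    0.0, teer_noise_cv * teer_g / area, size=n_inserts
                )
            for k in range(n_inserts):
                teer_rows.append(
                    {
                        "insert_id": f"T-d{dose:g}-day{day}-{k + 1}",
                        "dose_gy": float(dose),
                        "day": int(day),
                        "raw_ohm": float(raw[k]),
                    }
                )

    return SimulatedStudy(
        permeability_table=pd.DataFrame(perm_rows),
        teer_table=pd.DataFrame(teer_rows),
        provenance={
            "seed": int(seed),
            "n_inserts": n_inserts,
            "noise_cv": noise_cv,
            "teer_noise_cv": teer_noise_cv,
            "doses": [float(d) for d in doses],
            "days": [int(d) for d in days],
            "n_cell_free": n_cell_free,
        },
    )


#: typical wet tissue masses (mg) by age group and brain region
_TISSUE_MASS_MG = {
    ("adult", "cerebrum"): 200.0,
    ("adult", "cerebellum"): 60.0,
    ("infant", "cerebrum"): 120.0,
    ("infant", "cerebellum"): 35.0,
}

#: default plate calibration: reading = slope * (ng/ml) + intercept
_CAL_SLOPE = 2.0
_CAL_INTERCEPT = 50.0


def simulate_in_vivo_dataset(
    effects: EffectModel,
    *,
    seed: int,
    regions: Sequence[str] = REGIONS,
    ages: Sequence[str] = AGE_GROUPS,
    doses: Sequence[float] = DOSES_GY,
    timepoints: Sequence[str] = INVIVO_TIMEPOINTS,
    extract_volume_ml: float = 0.5,
) -> SimulatedStudy:
    """Simulate per-animal brain Evans-blue content and the standard plate.

    True tissue content (ng dye per mg tissue) is drawn lognormally around
    ``baseline × multiplier`` for each age × region × dose × timepoint group;
    the plate reading is produced through an invertible linear calibration
    whose 7-point standard series is emitted alongside, so the downstream
    quantification can recover content exactly when noise-free.
    """
    if seed is None:
        raise ValueError("a seed is required for simulation")
    for age in ages:
        for dose in doses:
            for tp in timepoints:
                if dose != 0.0:
                    # every irradiated cell must be resolvable (default 1.0)
                    effects.invivo_multiplier(age, dose, tp)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    animal = 0
    for age in ages:
        for region in regions:
            for dose in doses:
                for tp in timepoints:
                    mult = effects.invivo_multiplier(age, dose, tp)
                    mean = effects.baseline_evans_blue_ng_mg * mult
                    content = mean * _lognormal_factors(
                        rng, effects.noise_cv, effects.n_invivo
                    )
                    mass = rng.normal(
                        _TISSUE_MASS_MG[(age, region)],
                        0.05 * _TISSUE_MASS_MG[(age, region)],
                        size=effects.n_invivo,
                    )
                    mass = np.clip(mass, 1.0, None)
                    for c, m in zip(content, mass):
                        animal += 1
                        conc_ng_ml = c * m / extract_volume_ml
                        rows.append(
                            {
                                "animal_id": f"A{animal:04d}",
                                "age_group": age,
                                "region": region,
                                "dose_gy": float(dose),
                                "timepoint": tp,
                                "reading": _CAL_SLOPE * conc_ng_ml + _CAL_INTERCEPT,
                                "tissue_mass_mg": float(m),
                                "extract_volume_ml": extract_volume_ml,
                            }
                        )
    standards = pd.DataFrame(
        {
            "conc_ng_ml": STANDARD_CONCENTRATIONS,
            "reading": [
                _CAL_SLOPE * c + _CAL_INTERCEPT for c in STANDARD_CONCENTRATIONS
            ],
        }
    )
    return SimulatedStudy(
        invivo_table=pd.DataFrame(rows),
        standards_table=standards,
        provenance={"seed": int(seed), "noise_cv": effects.noise_cv,
                    "n_per_group": effects.n_invivo},
    )


def simulate_count_assays(
    effects: EffectModel,
    *,
    seed: int,
    doses: Sequence[float] = DOSES_GY,
    cep_timepoints: Sequence[str] = INVIVO_TIMEPOINTS,
    density_days: Sequence[int] = INVITRO_DAYS,
) -> SimulatedStudy:
    """Simulate the count-based endpoints as a single long table.

    CEP colonies are Poisson with rate ``(rate/10⁵ PBMC) × PBMC count``;
    SA-β-gal-positive cells are Binomial over the 400–500 cells counted per
    coverslip; cells-per-field are Poisson at ``density × field area``.
    """
    if seed is None:
        raise ValueError("a seed is required for simulation")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    for dose in doses:
        for tp in cep_timepoints:
            mult = effects.cep_multipliers.get((float(dose), tp), 1.0)
            rate = effects.baseline_cep_rate_per_1e5 * mult
            pbmc = rng.integers(400_000, 800_001, size=effects.n_cep)
            colonies = rng.poisson(rate * pbmc / 1e5)
            for i, (c, p) in enumerate(zip(colonies, pbmc)):
                rows.append(
                    {
                        "subject_id": f"cep-d{dose:g}-{tp}-{i + 1}",
                        "dose_gy": float(dose),
                        "timepoint": tp,
                        "assay": "cep",
                        "numerator": int(c),
                        "denominator": float(p),
                    }
                )

    for dose in doses:
        p = effects.baseline_senescence_fraction * effects.senescence_multipliers.get(
            float(dose), 1.0
        )
        if p > 1:
            raise ValueError(
                f"senescence fraction {p:.3f} > 1 at dose {dose:g} Gy"
            )
        counted = rng.integers(400, 501, size=effects.n_senescence_coverslips)
        positives = rng.binomial(counted, p)
        for i, (pos, n) in enumerate(zip(positives, counted)):
            rows.append(
                {
                    "subject_id": f"sen-d{dose:g}-{i + 1}",
                    "dose_gy": float(dose),
                    "timepoint": "d5",
                    "assay": "senescence",
                    "numerator": int(pos),
                    "denominator": float(n),
                }
            )

    for dose in doses:
        for day in density_days:
            mult = effects.density_multipliers.get((float(dose), int(day)), 1.0)
            lam = effects.baseline_density_mm2 * mult * effects.field_area_mm2
            cells = rng.poisson(lam, size=effects.n_density_fields)
            for i, c in enumerate(cells):
                rows.append(
                    {
                        "subject_id": f"den-d{dose:g}-day{day}-{i + 1}",
                        "dose_gy": float(dose),
                        "timepoint": f"d{day}",
                        "assay": "cell_density",
                        "numerator": int(c),
                        "denominator": effects.field_area_mm2,
                    }
                )

    return SimulatedStudy(
        counts_table=pd.DataFrame(rows),
        provenance={"seed": int(seed)},
    )


def simulate_study(
    kinetics: TrueKinetics | None = None,
    effects: EffectModel | None = None,
    *,
    seed: int,
    n_inserts: int = 3,
    noise_cv: float = 0.10,
) -> SimulatedStudy:
    """Run every generator with sub-seeds derived from ``seed`` and merge the
    tables into one :class:`SimulatedStudy`."""
    kinetics = kinetics if kinetics is not None else TrueKinetics()
    effects = effects if effects is not None else EffectModel()
    ss = np.random.SeedSequence(seed)
    s_perm, s_vivo, s_counts = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    perm = simulate_permeability_dataset(
        kinetics, n_inserts=n_inserts, noise_cv=noise_cv, seed=s_perm
    )
    vivo = simulate_in_vivo_dataset(effects, seed=s_vivo)
    counts = simulate_count_assays(effects, seed=s_counts)
    return SimulatedStudy(
        permeability_table=perm.permeability_table,
        teer_table=perm.teer_table,
        invivo_table=vivo.invivo_table,
        standards_table=vivo.standards_table,
        counts_table=counts.counts_table,
        provenance={
            "seed": int(seed),
            "permeability": perm.provenance,
            "invivo": vivo.provenance,
            "counts": counts.provenance,
        },
    )
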