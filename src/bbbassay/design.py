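"""Experimental design constants and true-parameter containers.

The geometry mirrors a 24-well transwell blood-brain-barrier co-culture
experiment: a 70 µl luminal (donor) compartment above an endothelial
monolayer grown on a 0.33 cm² insert, suspended in a 530 µl abluminal
(receiver) well.  Tracer flux is sampled at 20, 40 and 60 min, the insert
being moved to a fresh receiver well at each sampling time.  Two tracers are
run in parallel: sodium fluorescein (10 µg/ml, paracellular marker) and
Evans blue bound to albumin (165 µg/ml, transcellular/leakage marker).

Radiation doses are 0 (sham), 0.1, 2 and 10 Gy; in vitro endpoints are read
1, 2, 3 and 5 days post-irradiation, in vivo endpoints at 1 day and 1, 4 and
26 weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

TRACER_FLUORESCEIN = "fluorescein"
TRACER_EB_ALBUMIN = "eb_albumin"
TRACERS = (TRACER_FLUORESCEIN, TRACER_EB_ALBUMIN)

DOSES_GY = (0.0, 0.1, 2.0, 10.0)
INVITRO_DAYS = (1, 2, 3, 5)
INVIVO_TIMEPOINTS = ("1d", "1w", "4w", "26w")
AGE_GROUPS = ("adult", "infant")
REGIONS = ("cerebrum", "cerebellum")

#: nominal initial donor concentrations, µg/ml
DONOR_CONCENTRATIONS = {TRACER_FLUORESCEIN: 10.0, TRACER_EB_ALBUMIN: 165.0}


@dataclass(frozen=True)
class AssayDesign:
    """Geometry, tracer dose and sampling schedule of one transwell assay.

    Permeability coefficients (Pe) are handled on the 10⁻⁶ cm/s scale
    throughout; permeability-surface products (PS) in µl/min.
    """

    luminal_volume_ul: float = 70.0
    abluminal_volume_ul: float = 530.0
    insert_area_cm2: float = 0.33
    sample_times_min: tuple[float, ...] = (20.0, 40.0, 60.0)
    donor_concentration: float = 10.0
    tracer_label: str = TRACER_FLUORESCEIN

    def __post_init__(self) -> None:
        if self.luminal_volume_ul <= 0 or self.abluminal_volume_ul <= 0:
            raise ValueError("compartment volumes must be positive")
        if self.insert_area_cm2 <= 0:
            raise ValueError("insert area must be positive")
        if self.donor_concentration <= 0:
            raise ValueError("donor concentration must be positive")
        times = self.sample_times_min
        if len(times) < 1 or times[0] <= 0 or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise ValueError("sample times must be strictly increasing and > 0")
        if self.tracer_label not in TRACERS:
            raise ValueError(f"unknown tracer {self.tracer_label!r}")


def default_designs() -> dict[str, AssayDesign]:
    """One :class:`AssayDesign` per tracer with the study's geometry."""
    return {
        t: AssayDesign(donor_concentration=DONOR_CONCENTRATIONS[t], tracer_label=t)
        for t in TRACERS
    }


def pe_to_ps(pe_1e6_cm_s: float, area_cm2: float) -> float:
    """Convert a permeability coefficient (10⁻⁶ cm/s) into a PS product (µl/min).

    PS = Pe · A, with 10⁻⁶ cm/s · cm² = 10⁻⁶ cm³/s = 10⁻³ µl/s = 0.06 µl/min.
    """
    return pe_1e6_cm_s * area_cm2 * 0.06


def _default_pe_multipliers() -> dict[tuple[str, float, int], float]:
    # Dose- and day-dependent fold elevation of endothelial Pe over sham.
    # Pattern: no change on day 1; largest rise on day 2 at 2 and 10 Gy,
    # persisting through days 3 and 5; the 0.1 Gy effect appears only from
    # day 3 and only for the paracellular tracer (fluorescein).
    mult: dict[tuple[str, float, int], float] = {}
    for tracer in TRACERS:
        for dose, by_day in (
            (2.0, {2: 2.0, 3: 1.8, 5: 1.6}),
            (10.0, {2: 2.5, 3: 2.2, 5: 2.0}),
        ):
            for day, m in by_day.items():
                mult[(tracer, dose, day)] = m
    for day in (3, 5):
        mult[(TRACER_FLUORESCEIN, 0.1, day)] = 1.5
    return mult


@dataclass
class TrueKinetics:
    """Ground-truth transport parameters of the simulated transwell plate.

    ``pe_baseline`` are the sham endothelial permeability coefficients
    (10⁻⁶ cm/s); ``pe_insert`` those of the cell-free coated membrane.
    ``teer_baseline`` is the sham transendothelial resistance (Ω·cm²),
    ``teer_between_sd`` its between-insert biological spread, and
    ``blank_teer`` the resistance of an empty coated insert that the
    analysis subtracts.
    """

    pe_baseline: Mapping[str, float] = field(
        default_factory=lambda: {TRACER_FLUORESCEIN: 0.21, TRACER_EB_ALBUMIN: 0.043}
    )
    pe_insert: Mapping[str, float] = field(
        default_factory=lambda: {TRACER_FLUORESCEIN: 20.0, TRACER_EB_ALBUMIN: 5.0}
    )
    pe_multipliers: Mapping[tuple[str, float, int], float] = field(
        default_factory=_default_pe_multipliers
    )
    teer_baseline: float = 382.6
    teer_between_sd: float = 80.4
    teer_multipliers: Mapping[tuple[float, int], float] = field(
        default_factory=lambda: {(10.0, 2): 0.7}
    )
    blank_teer: float = 70.0

    def __post_init__(self) -> None:
        for tracer, pe in self.pe_baseline.items():
            if pe <= 0:
                raise ValueError(f"pe_baseline[{tracer!r}] must be > 0")
            pins = self.pe_insert.get(tracer)
            if pins is None or pins <= 0:
                raise ValueError(f"pe_insert[{tracer!r}] must be > 0")
        if self.teer_baseline < 0 or self.blank_teer < 0:
            raise ValueError("resistances must be non-negative")
        if self.teer_between_sd < 0:
            raise ValueError("teer_between_sd must be non-negative")
        if any(m <= 0 for m in self.pe_multipliers.values()):
            raise ValueError("pe multipliers must be positive")

    def pe_true(self, tracer: str, dose: float, day: int) -> float:
        return self.pe_baseline[tracer] * self.pe_multipliers.get(
            (tracer, float(dose), int(day)), 1.0
        )

    def teer_true(self, dose: float, day: int) -> float:
        return self.teer_baseline * self.teer_multipliers.get(
            (float(dose), int(day)), 1.0
        )


def _default_invivo_multipliers() -> dict[tuple[str, float, str], float]:
    # Evans-blue extravasation fold change over sham: adults leak ~2-fold at
    # 1 week for every dose; in infants the same effect is delayed to week 4;
    # full recovery by 26 weeks in both age groups.
    mult: dict[tuple[str, float, str], float] = {}
    for dose in DOSES_GY[1:]:
        mult[("adult", dose, "1w")] = 2.0
        mult[("infant", dose, "4w")] = 2.0
    return mult


def _default_cep_multipliers() -> dict[tuple[float, str], float]:
    # Circulating endothelial progenitor colonies drop one day after 0.1 and
    # 2 Gy exposure and recover by 26 weeks.
    return {
        (0.1, "1d"): 0.5,
        (2.0, "1d"): 0.5,
        (2.0, "4w"): 0.6,
    }


def _default_density_multipliers() -> dict[tuple[float, int], float]:
    # Endothelial / glial cell density declines from day 3 at 2 and 10 Gy.
    return {
        (2.0, 3): 0.85,
        (2.0, 5): 0.75,
        (10.0, 3): 0.8,
        (10.0, 5): 0.65,
    }


@dataclass
class EffectModel:
    """Baselines, group effect multipliers, noise and group sizes for the
    non-transwell endpoints of the simulated study.

    ``senescence_multipliers`` scale the sham SA-β-gal-positive fraction
    (relative increases of 30% and 40% at 2 and 10 Gy, read on day 5).
    The sham tissue Evans-blue content is a free parameter; the study
    reports only relative changes.
    """

    baseline_evans_blue_ng_mg: float = 15.0
    baseline_senescence_fraction: float = 0.25
    baseline_cep_rate_per_1e5: float = 2.0
    baseline_density_mm2: float = 800.0
    invivo_multipliers: Mapping[tuple[str, float, str], float] = field(
        default_factory=_default_invivo_multipliers
    )
    senescence_multipliers: Mapping[float, float] = field(
        default_factory=lambda: {2.0: 1.3, 10.0: 1.4}
    )
    cep_multipliers: Mapping[tuple[float, str], float] = field(
        default_factory=_default_cep_multipliers
    )
    density_multipliers: Mapping[tuple[float, int], float] = field(
        default_factory=_default_density_multipliers
    )
    noise_cv: float = 0.20
    n_invivo: int = 12
    n_cep: int = 8
    n_senescence_coverslips: int = 19
    n_density_fields: int = 12
    field_area_mm2: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.baseline_senescence_fraction < 1:
            raise ValueError("baseline senescence fraction must be in (0, 1)")
        for name in ("baseline_evans_blue_ng_mg", "baseline_density_mm2",
                     "field_area_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_cep_rate_per_1e5 < 0:
            raise ValueError("baseline_cep_rate_per_1e5 must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for table in (self.invivo_multipliers, self.senescence_multipliers,
                      self.cep_multipliers, self.density_multipliers):
            if any(m <= 0 for m in table.values()):
                raise ValueError("effect multipliers must be positive")
        for n in (self.n_invivo, self.n_cep, self.n_senescence_coverslips,
                  self.n_density_fields):
            if n < 2:
                raise ValueError("group sizes entering statistics must be >= 2")

    def invivo_multiplier(self, age: str, dose: float, timepoint: str) -> float:
        return self.invivo_multipliers.get((age, float(dose), timepoint), 1.0)
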