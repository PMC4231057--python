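"""Run configuration: a single YAML file overriding the named defaults.

All assay constants (volumes, area, sampling times, tracer doses, blank
TEER) are defaults of the domain types, never hard-coded in computation, so
a config can retarget the pipeline to a different plate geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .design import AssayDesign, EffectModel, TrueKinetics, default_designs

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Path = Path("bbbassay_out")
    designs: dict[str, AssayDesign] = field(default_factory=default_designs)
    kinetics: TrueKinetics = field(default_factory=TrueKinetics)
    effects: EffectModel = field(default_factory=EffectModel)
    n_inserts: int = 3
    noise_cv: float = 0.10
    bonferroni_family: str = "all"          # or "per_timepoint"
    bootstrap_resamples: int = 2000


def _apply_overrides(obj, overrides: dict):
    valid = {f.name for f in fields(obj)}
    unknown = set(overrides) - valid
    if unknown:
        raise KeyError(f"unknown {type(obj).__name__} fields: {sorted(unknown)}")
    return replace(obj, **overrides)


def load_config(path: str | Path | None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file (or defaults when None).

    Recognized top-level keys: ``seed``, ``outdir``, ``n_inserts``,
    ``noise_cv``, ``bonferroni_family``, ``bootstrap_resamples``, plus
    ``design.<tracer>``, ``kinetics`` and ``effects`` override mappings whose
    keys must name dataclass fields of the corresponding type.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    simple = {k: raw[k] for k in (
        "seed", "n_inserts", "noise_cv", "bonferroni_family", "bootstrap_resamples"
    ) if k in raw}
    for k, v in simple.items():
        setattr(cfg, k, v)
    if "outdir" in raw:
        cfg.outdir = Path(raw["outdir"])
    for tracer, over in (raw.get("design") or {}).items():
        if tracer not in cfg.designs:
            raise KeyError(f"unknown tracer {tracer!r} in design overrides")
        cfg.designs[tracer] = _apply_overrides(cfg.designs[tracer], over)
    if "kinetics" in raw:
        cfg.kinetics = _apply_overrides(cfg.kinetics, raw["kinetics"])
    if "effects" in raw:
        cfg.effects = _apply_overrides(cfg.effects, raw["effects"])
    return cfg
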