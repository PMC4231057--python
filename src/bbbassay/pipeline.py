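"""Stage functions tying the modules into a file-based pipeline.

Each stage is a pure function of its input tables plus config: it reads the
named CSV schemas from a run directory, computes, and writes result tables
with a provenance block.  The thin CLI in :mod:`bbbassay.cli` only dispatches
to these.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .cellular import summarize_counts_table
from .config import RunConfig
from .extravasation import fit_standard_curve, fold_change_vs_sham, quantify_invivo_table
from .io import load_table, write_provenance, write_table
from .permeability import compute_teer_table, run_permeability_pipeline
from .simulate import simulate_study
from .stats import bonferroni_vs_sham, one_way_anova, two_way_anova

__all__ = [
    "stage_simulate", "stage_permeability", "stage_evansblue",
    "stage_assays", "stage_stats", "stage_report", "DependencyError",
]


class DependencyError(RuntimeError):
    """An upstream stage's outputs are missing from the run directory."""


def _require(outdir: Path, name: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise DependencyError(
            f"{name} not found in {outdir}; run the upstream stage first"
        )
    return p


def _provenance(cfg: RunConfig, stage: str, extra: dict | None = None) -> dict:
    return {
        "stage": stage, "seed": cfg.seed, "version": __version__,
        "n_inserts": cfg.n_inserts, "noise_cv": cfg.noise_cv,
    } | (extra or {})


def stage_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Forward-simulate every assay table into the run directory."""
    study = simulate_study(
        cfg.kinetics, cfg.effects, seed=cfg.seed,
        n_inserts=cfg.n_inserts, noise_cv=cfg.noise_cv,
    )
    out = {}
    for name, df in (
        ("permeability.csv", study.permeability_table),
        ("teer.csv", study.teer_table),
        ("invivo.csv", study.invivo_table),
        ("standards.csv", study.standards_table),
        ("counts.csv", study.counts_table),
    ):
        out[name] = write_table(df, cfg.outdir / name)
    write_provenance(_provenance(cfg, "simulate", study.provenance),
                     cfg.outdir / "simulate.provenance.json")
    return out


def stage_permeability(cfg: RunConfig) -> dict[str, Path]:
    """Raw transwell tables → per-insert Pe and normalized TEER tables."""
    perm = load_table(_require(cfg.outdir, "permeability.csv"), "permeability")
    results = run_permeability_pipeline(perm, designs=cfg.designs)
    results = results.assign(
        cleared_volumes_ul=results["cleared_volumes_ul"].map(
            lambda v: ";".join(f"{x:.6g}" for x in v)
        )
    )
    out = {"permeability_results.csv": write_table(
        results, cfg.outdir / "permeability_results.csv")}
    teer = load_table(_require(cfg.outdir, "teer.csv"), "teer")
    design = next(iter(cfg.designs.values()))
    teer_res = compute_teer_table(
        teer, area_cm2=design.insert_area_cm2, blank=cfg.kinetics.blank_teer
    )
    out["teer_results.csv"] = write_table(teer_res, cfg.outdir / "teer_results.csv")
    write_provenance(_provenance(cfg, "permeability"),
                     cfg.outdir / "permeability.provenance.json")
    return out


def stage_evansblue(cfg: RunConfig) -> dict[str, Path]:
    """Plate readings → ng/mg tissue plus fold-changes vs sham."""
    standards = load_table(_require(cfg.outdir, "standards.csv"), "standards")
    invivo = load_table(_require(cfg.outdir, "invivo.csv"), "invivo")
    curve = fit_standard_curve(standards)
    quantified = quantify_invivo_table(invivo, curve)
    folds = fold_change_vs_sham(
        quantified, "evans_blue_ng_mg",
        stratify_by=("age_group", "region", "timepoint"),
        n_boot=cfg.bootstrap_resamples, seed=cfg.seed,
    )
    out = {
        "evansblue_results.csv": write_table(
            quantified, cfg.outdir / "evansblue_results.csv"),
        "evansblue_foldchange.csv": write_table(
            folds, cfg.outdir / "evansblue_foldchange.csv"),
    }
    write_provenance(
        _provenance(cfg, "evansblue",
                    {"curve_slope": curve.slope, "curve_intercept": curve.intercept,
                     "curve_r2": curve.r2}),
        cfg.outdir / "evansblue.provenance.json")
    return out


def stage_assays(cfg: RunConfig) -> dict[str, Path]:
    """Counts table → per-subject endpoint values."""
    counts = load_table(_require(cfg.outdir, "counts.csv"), "counts")
    results = summarize_counts_table(counts)
    out = {"assay_results.csv": write_table(results, cfg.outdir / "assay_results.csv")}
    write_provenance(_provenance(cfg, "assays"),
                     cfg.outdir / "assays.provenance.json")
    return out


def build_grouped(cfg: RunConfig) -> pd.DataFrame:
    """Assemble the long (subject, dose, timepoint, endpoint, value) table
    from whichever upstream result tables exist in the run directory."""
    frames = []
    p = cfg.outdir / "permeability_results.csv"
    if p.exists():
        pe = pd.read_csv(p)
        pe = pe[~pe["excluded"].astype(bool)]
        frames.append(pd.DataFrame({
            "subject_id": pe["insert_id"], "dose_gy": pe["dose_gy"],
            "timepoint": "d" + pe["day"].astype(int).astype(str),
            "endpoint": "pe_" + pe["tracer"], "value": pe["pe"],
        }))
    p = cfg.outdir / "teer_results.csv"
    if p.exists():
        te = pd.read_csv(p)
        frames.append(pd.DataFrame({
            "subject_id": te["insert_id"], "dose_gy": te["dose_gy"],
            "timepoint": "d" + te["day"].astype(int).astype(str),
            "endpoint": "teer", "value": te["teer"],
        }))
    p = cfg.outdir / "evansblue_results.csv"
    if p.exists():
        eb = pd.read_csv(p)
        frames.append(pd.DataFrame({
            "subject_id": eb["animal_id"], "dose_gy": eb["dose_gy"],
            "timepoint": eb["timepoint"],
            "endpoint": ("evans_blue_" + eb["age_group"] + "_" + eb["region"]),
            "value": eb["evans_blue_ng_mg"],
        }))
    p = cfg.outdir / "assay_results.csv"
    if p.exists():
        ar = pd.read_csv(p)
        frames.append(ar[["subject_id", "dose_gy", "timepoint", "endpoint", "value"]])
    if not frames:
        raise DependencyError("no upstream result tables found; run them first")
    return pd.concat(frames, ignore_index=True)


def stage_stats(cfg: RunConfig) -> dict[str, Path]:
    """Grouped measurements → per-endpoint ANOVA and Bonferroni post-tests.

    Endpoints observed at >= 2 timepoints get a two-way dose × time ANOVA,
    single-timepoint endpoints a one-way ANOVA; all get dose-vs-sham
    Bonferroni comparisons.
    """
    grouped = build_grouped(cfg)
    write_table(grouped, cfg.outdir / "grouped.csv")
    anova_rows, posthoc_frames = [], []
    for endpoint, sub in grouped.groupby("endpoint", sort=True):
        if sub["timepoint"].nunique() >= 2:
            res = two_way_anova(sub, factors=("dose_gy", "timepoint"))
            post = bonferroni_vs_sham(sub, anova=res, family=cfg.bonferroni_family)
        else:
            res = one_way_anova(sub)
            post = bonferroni_vs_sham(
                sub.assign(timepoint=sub["timepoint"]), anova=res,
                family="per_timepoint",
            )
        for effect, row in res.factors.iterrows():
            anova_rows.append({"endpoint": endpoint, "effect": effect} | row.to_dict())
        posthoc_frames.append(post.assign(endpoint=endpoint))
    out = {
        "anova.csv": write_table(pd.DataFrame(anova_rows), cfg.outdir / "anova.csv"),
        "posthoc.csv": write_table(
            pd.concat(posthoc_frames, ignore_index=True), cfg.outdir / "posthoc.csv"),
    }
    write_provenance(_provenance(cfg, "stats",
                                 {"family": cfg.bonferroni_family}),
                     cfg.outdir / "stats.provenance.json")
    return out


def stage_report(cfg: RunConfig) -> str:
    """Render group means ± SD with significance stars per endpoint."""
    grouped_path = _require(cfg.outdir, "grouped.csv")
    posthoc_path = _require(cfg.outdir, "posthoc.csv")
    grouped = pd.read_csv(grouped_path)
    posthoc = pd.read_csv(posthoc_path)
    lines = []
    for endpoint, sub in grouped.groupby("endpoint", sort=True):
        lines.append(f"== {endpoint} ==")
        summary = sub.groupby(["timepoint", "dose_gy"], sort=True)["value"].agg(
            ["mean", "std", "count"])
        stars = posthoc[posthoc["endpoint"] == endpoint].set_index(
            ["timepoint", "dose_gy"])["stars"]
        for (tp, dose), row in summary.iterrows():
            star = stars.get((tp, dose), "")
            star = "" if star in ("ns", None) else (star or "")
            lines.append(
                f"  {tp:>4} {dose:>5.1f} Gy: {row['mean']:10.3f} ± "
                f"{row['std'] if pd.notna(row['std']) else 0:8.3f}"
                f"  (n={int(row['count'])}) {star}"
            )
    text = "\n".join(lines) + "\n"
    (cfg.outdir / "report.txt").write_text(text)
    return text
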