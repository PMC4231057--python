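"""Group statistics for dose × time designs: one-way and two-way
fixed-effects ANOVA followed by Bonferroni multiple-comparison post-tests
against the sham (0 Gy) group at matched time points.

Two-way ANOVA uses Type III sums of squares under sum-to-zero factor coding
(the convention of the GUI packages common in this field), which reduces to
the textbook decomposition on balanced tables.  Post-tests use the pooled
error variance of the full interaction model — identical to the classical
"Bonferroni post-test" following ANOVA — with family size equal to the
number of dose-vs-sham comparisons across all time points (a per-timepoint
family is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "star_code",
    "one_way_anova",
    "two_way_anova",
    "bonferroni_vs_sham",
]


def star_code(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaResult:
    """Per-factor F tests plus (optionally) a dose-vs-sham comparison table."""

    factors: pd.DataFrame            # index: effect; columns F, df_num, df_den, p
    comparisons: pd.DataFrame | None = None
    residual_ms: float = float("nan")
    residual_df: int = 0
    meta: dict = field(default_factory=dict)


def _check_groups(table: pd.DataFrame, cols: list[str], value_col: str) -> None:
    counts = table.groupby(cols, sort=True)[value_col].count()
    too_small = counts[counts < 2]
    if len(too_small):
        raise ValueError(
            f"groups with < 2 observations: {list(too_small.index)}"
        )
    if not np.isfinite(table[value_col].to_numpy(float)).all():
        raise ValueError("non-finite endpoint values")


def one_way_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "dose_gy",
    control: float | str | None = 0.0,
) -> AnovaResult:
    """One-way fixed-effects ANOVA with Bonferroni comparisons vs control.

    ``control`` selects the reference level for the pairwise post-tests
    (``None`` skips them).  The post-test t statistics use the ANOVA's
    pooled within-group variance; adjusted p is ``min(1, m·p)`` with m the
    number of comparisons.
    """
    _check_groups(table, [group_col], value_col)
    groups = {k: g[value_col].to_numpy(float) for k, g in table.groupby(group_col, sort=True)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    f_stat, p = sps.f_oneway(*groups.values())
    k = len(groups)
    n = sum(len(v) for v in groups.values())
    df_between, df_within = k - 1, n - k
    grand = np.concatenate(list(groups.values()))
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    ms_within = ss_within / df_within
    # identical group means give 0/0 in scipy; define F = 0, p = 1
    if not np.isfinite(f_stat):
        within_var = ms_within
        between = sum(len(v) * (v.mean() - grand.mean()) ** 2 for v in groups.values())
        f_stat = 0.0 if between == 0 or within_var == 0 else f_stat
        p = 1.0 if f_stat == 0.0 else p
    factors = pd.DataFrame(
        {"F": [float(f_stat)], "df_num": [df_between], "df_den": [df_within],
         "p": [float(p)]},
        index=pd.Index([group_col], name="effect"),
    )
    comparisons = None
    if control is not None:
        if control not in groups:
            raise ValueError(f"control group {control!r} absent")
        ref = groups[control]
        rows = []
        others = [g for g in groups if g != control]
        m = len(others)
        for g in others:
            v = groups[g]
            se = np.sqrt(ms_within * (1 / len(v) + 1 / len(ref)))
            diff = v.mean() - ref.mean()
            t = diff / se if se > 0 else 0.0
            p_raw = 2 * sps.t.sf(abs(t), df_within) if se > 0 else 1.0
            p_adj = min(1.0, m * p_raw)
            rows.append(
                {group_col: g, "mean_diff": float(diff), "t": float(t),
                 "p_raw": float(p_raw), "p_adj": float(p_adj),
                 "stars": star_code(p_adj)}
            )
        comparisons = pd.DataFrame(rows)
    return AnovaResult(
        factors=factors, comparisons=comparisons,
        residual_ms=float(ms_within), residual_df=int(df_within),
        meta={"design": "one_way", "group_col": group_col},
    )


def two_way_anova(
    table: pd.DataFrame,
    factors: tuple[str, str] = ("dose_gy", "timepoint"),
    value_col: str = "value",
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction, Type III SS under
    sum-to-zero coding.

    Every factor-level cell must be non-empty; an empty cell is reported by
    name.  On balanced tables the Type III decomposition coincides with the
    textbook sequential one.
    """
    a, b = factors
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = table.groupby([a, b], sort=True)[value_col].count()
    full = pd.MultiIndex.from_product(
        [table[a].unique(), table[b].unique()], names=[a, b]
    )
    empty = full.difference(cells.index)
    if len(empty):
        raise ValueError(f"empty design cells: {list(empty)}")
    _check_groups(table, [a, b], value_col)

    y = table[value_col].to_numpy(float)
    n_cells = int(cells.shape[0])
    if np.ptp(y) == 0:
        # constant response: every effect is exactly null
        factors_df = pd.DataFrame(
            {"F": 0.0,
             "df_num": [table[a].nunique() - 1, table[b].nunique() - 1,
                        (table[a].nunique() - 1) * (table[b].nunique() - 1)],
             "df_den": len(table) - n_cells, "p": 1.0},
            index=pd.Index([a, b, f"{a}:{b}"], name="effect"),
        )
        return AnovaResult(
            factors=factors_df, residual_ms=0.0,
            residual_df=len(table) - n_cells,
            meta={"design": "two_way", "factors": factors},
        )

    d = pd.DataFrame(
        {"_y": y,
         "_a": table[a].astype(str).to_numpy(),
         "_b": table[b].astype(str).to_numpy()}
    )
    model = smf.ols("_y ~ C(_a, Sum) * C(_b, Sum)", data=d).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    resid_df = int(aov.loc["Residual", "df"])
    resid_ms = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    name_map = {"C(_a, Sum)": a, "C(_b, Sum)": b,
                "C(_a, Sum):C(_b, Sum)": f"{a}:{b}"}
    rows = []
    for raw_name, name in name_map.items():
        f_val = float(aov.loc[raw_name, "F"])
        p_val = float(aov.loc[raw_name, "PR(>F)"])
        if not np.isfinite(f_val):  # zero residual variance, equal means
            f_val, p_val = 0.0, 1.0
        rows.append({"effect": name, "F": f_val,
                     "df_num": int(aov.loc[raw_name, "df"]),
                     "df_den": resid_df, "p": p_val})
    factors_df = pd.DataFrame(rows).set_index("effect")
    return AnovaResult(
        factors=factors_df, residual_ms=resid_ms, residual_df=resid_df,
        meta={"design": "two_way", "factors": factors},
    )


def pooled_error(
    table: pd.DataFrame, cell_cols: list[str], value_col: str
) -> tuple[float, int]:
    """Pooled within-cell variance and its df — the residual mean square of
    the full fixed-effects interaction model."""
    groups = table.groupby(cell_cols, sort=True)[value_col]
    ss = float(sum(((v - v.mean()) ** 2).sum() for _, v in groups))
    df = int(len(table) - groups.ngroups)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    return ss / df, df


def bonferroni_vs_sham(
    table: pd.DataFrame,
    anova: AnovaResult | None = None,
    dose_col: str = "dose_gy",
    time_col: str = "timepoint",
    value_col: str = "value",
    sham_dose: float = 0.0,
    family: str = "all",
) -> pd.DataFrame:
    """Bonferroni post-tests of every dose against sham at the same time point.

    The t statistic for each comparison uses the ANOVA pooled error variance
    (taken from ``anova`` when given, otherwise recomputed as the within-cell
    residual of the full interaction model — the same quantity).  The family
    size is doses × timepoints with ``family="all"`` (the default, covering
    every starred comparison of a dose-time figure) or doses only with
    ``family="per_timepoint"``.
    """
    if family not in ("all", "per_timepoint"):
        raise ValueError("family must be 'all' or 'per_timepoint'")
    _check_groups(table, [dose_col, time_col], value_col)
    timepoints = list(pd.unique(table[time_col]))
    doses = sorted(d for d in table[dose_col].unique() if d != sham_dose)
    if not doses:
        raise ValueError("no non-sham dose groups")
    for tp in timepoints:
        sub = table[table[time_col] == tp]
        if not (sub[dose_col] == sham_dose).any():
            raise ValueError(f"no sham group at timepoint {tp!r}")
    if anova is not None and np.isfinite(anova.residual_ms):
        ms, df = anova.residual_ms, anova.residual_df
    else:
        ms, df = pooled_error(table, [dose_col, time_col], value_col)
    m = len(doses) * (len(timepoints) if family == "all" else 1)
    rows = []
    for tp in timepoints:
        sub = table[table[time_col] == tp]
        sham = sub.loc[sub[dose_col] == sham_dose, value_col].to_numpy(float)
        for dose in doses:
            v = sub.loc[sub[dose_col] == dose, value_col].to_numpy(float)
            if v.size == 0:
                continue
            diff = v.mean() - sham.mean()
            se = np.sqrt(ms * (1 / v.size + 1 / sham.size))
            t = diff / se if se > 0 else 0.0
            p_raw = 2 * sps.t.sf(abs(t), df) if se > 0 else 1.0
            p_adj = min(1.0, m * p_raw)
            rows.append(
                {time_col: tp, dose_col: float(dose), "mean_diff": float(diff),
                 "t": float(t), "df": int(df), "p_raw": float(p_raw),
                 "m": int(m), "p_adj": float(p_adj), "stars": star_code(p_adj)}
            )
    return pd.DataFrame(rows)
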