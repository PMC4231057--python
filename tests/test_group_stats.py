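"""ANOVA and Bonferroni post-tests against hand-computed sums of squares and
a null-simulation check of family-wise error control."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from bbbassay import bonferroni_vs_sham, one_way_anova, star_code, two_way_anova
from bbbassay.stats import pooled_error


def balanced_table(cells, n_label="v"):
    """cells: {(a, b): [values]} -> long table."""
    rows = []
    for i, ((a, b), vals) in enumerate(cells.items()):
        for v in vals:
            rows.append({"dose_gy": a, "timepoint": b, "value": float(v)})
    return pd.DataFrame(rows)


def hand_two_way_ss(table):
    """Textbook balanced two-way ANOVA sums of squares (independent oracle)."""
    y = table["value"].to_numpy()
    grand = y.mean()
    a_levels = sorted(table["dose_gy"].unique())
    b_levels = sorted(table["timepoint"].unique())
    n = len(table) // (len(a_levels) * len(b_levels))
    ss_a = sum(
        len(b_levels) * n * (table.loc[table["dose_gy"] == a, "value"].mean() - grand) ** 2
        for a in a_levels
    )
    ss_b = sum(
        len(a_levels) * n * (table.loc[table["timepoint"] == b, "value"].mean() - grand) ** 2
        for b in b_levels
    )
    ss_cells = 0.0
    ss_err = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = table.loc[
                (table["dose_gy"] == a) & (table["timepoint"] == b), "value"
            ]
            ss_cells += n * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    return ss_a, ss_b, ss_ab, ss_err


class TestOneWay:
    def test_identical_groups(self):
        t = pd.DataFrame({"dose_gy": [0.0] * 3 + [2.0] * 3, "value": [5.0] * 6})
        res = one_way_anova(t)
        assert res.factors["F"].iloc[0] == 0.0
        assert res.factors["p"].iloc[0] == 1.0

    def test_matches_hand_computed_mean_squares(self):
        groups = {0.0: [1.0, 2.0, 3.0], 2.0: [4.0, 6.0, 8.0], 10.0: [9.0, 10.0, 14.0]}
        t = pd.DataFrame(
            [{"dose_gy": k, "value": v} for k, vals in groups.items() for v in vals]
        )
        grand = t["value"].mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_expected = (ssb / 2) / (ssw / 6)
        res = one_way_anova(t)
        assert res.factors["F"].iloc[0] == pytest.approx(f_expected, rel=1e-12)
        assert res.factors["df_num"].iloc[0] == 2
        assert res.factors["df_den"].iloc[0] == 6

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {"dose_gy": np.repeat([0.0, 2.0, 10.0], 5), "value": rng.normal(size=15)}
        )
        f1 = one_way_anova(t).factors["F"].iloc[0]
        f2 = one_way_anova(t.assign(value=t["value"] + 100.0)).factors["F"].iloc[0]
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_control_comparisons_use_pooled_variance(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(
            {"dose_gy": np.repeat([0.0, 2.0, 10.0], 4), "value": rng.normal(size=12)}
        )
        res = one_way_anova(t, control=0.0)
        assert len(res.comparisons) == 2
        assert (res.comparisons["p_adj"] >= res.comparisons["p_raw"]).all()
        assert (res.comparisons["p_adj"] <= 1.0).all()


class TestTwoWay:
    def test_balanced_toy_matches_hand_ss(self):
        cells = {
            (0.0, "t1"): [1, 2], (0.0, "t2"): [3, 4],
            (2.0, "t1"): [5, 6], (2.0, "t2"): [9, 10],
        }
        t = balanced_table(cells)
        ss_a, ss_b, ss_ab, ss_err = hand_two_way_ss(t)
        df_err = 4
        res = two_way_anova(t)
        assert res.factors.loc["dose_gy", "F"] == pytest.approx(
            (ss_a / 1) / (ss_err / df_err), rel=1e-10)
        assert res.factors.loc["timepoint", "F"] == pytest.approx(
            (ss_b / 1) / (ss_err / df_err), rel=1e-10)
        assert res.factors.loc["dose_gy:timepoint", "F"] == pytest.approx(
            (ss_ab / 1) / (ss_err / df_err), rel=1e-10)
        assert res.residual_ms == pytest.approx(ss_err / df_err, rel=1e-10)

    def test_equal_means_give_zero_f(self):
        cells = {(a, b): [5.0, 5.0] for a in (0.0, 2.0) for b in ("t1", "t2")}
        res = two_way_anova(balanced_table(cells))
        assert (res.factors["F"] == 0.0).all()

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        t = balanced_table(
            {(a, b): rng.normal(size=3) for a in (0.0, 2.0, 10.0) for b in ("t1", "t2")}
        )
        res1 = two_way_anova(t)
        res2 = two_way_anova(t.sample(frac=1.0, random_state=5))
        pd.testing.assert_frame_equal(res1.factors, res2.factors)

    def test_empty_cell_named_in_error(self):
        t = balanced_table(
            {(0.0, "t1"): [1, 2], (0.0, "t2"): [3, 4], (2.0, "t1"): [5, 6]}
        )
        with pytest.raises(ValueError, match="t2"):
            two_way_anova(t)

    def test_type3_equals_sequential_on_balanced(self):
        rng = np.random.default_rng(3)
        t = balanced_table(
            {(a, b): rng.normal(size=4) for a in (0.0, 0.1, 2.0, 10.0)
             for b in ("t1", "t2", "t3")}
        )
        res = two_way_anova(t)
        model = smf.ols(
            "value ~ C(dose_gy, Sum) * C(timepoint, Sum)",
            data=t.assign(dose_gy=t["dose_gy"].astype(str)),
        ).fit()
        seq = sm.stats.anova_lm(model, typ=1)
        for raw, name in [
            ("C(dose_gy, Sum)", "dose_gy"),
            ("C(timepoint, Sum)", "timepoint"),
            ("C(dose_gy, Sum):C(timepoint, Sum)", "dose_gy:timepoint"),
        ]:
            assert res.factors.loc[name, "F"] == pytest.approx(
                seq.loc[raw, "F"], rel=1e-10)


class TestBonferroni:
    def make_table(self, rng, effect=0.0, doses=(0.0, 2.0), tps=("t1", "t2"), n=4):
        rows = []
        for d in doses:
            for tp in tps:
                for v in rng.normal(effect if d > 0 else 0.0, 1.0, n):
                    rows.append({"dose_gy": d, "timepoint": tp, "value": v})
        return pd.DataFrame(rows)

    def test_adjustment_is_min_one_m_times_p(self, rng):
        t = self.make_table(rng, effect=1.0, doses=(0.0, 0.1, 2.0, 10.0))
        out = bonferroni_vs_sham(t, family="all")
        assert (out["m"] == 3 * 2).all()
        np.testing.assert_allclose(
            out["p_adj"], np.minimum(1.0, out["m"] * out["p_raw"])
        )

    def test_identical_groups_give_p_one(self):
        t = pd.DataFrame(
            {"dose_gy": [0.0, 0.0, 2.0, 2.0], "timepoint": ["t1"] * 4,
             "value": [1.0, 2.0, 1.0, 2.0]}
        )
        out = bonferroni_vs_sham(t, family="per_timepoint")
        assert out["p_adj"].iloc[0] == 1.0

    def test_per_timepoint_family_is_smaller(self, rng):
        t = self.make_table(rng, doses=(0.0, 2.0, 10.0), tps=("t1", "t2", "t3"))
        all_fam = bonferroni_vs_sham(t, family="all")
        per_tp = bonferroni_vs_sham(t, family="per_timepoint")
        assert (all_fam["m"] == 6).all() and (per_tp["m"] == 2).all()

    def test_missing_sham_raises(self, rng):
        t = self.make_table(rng)
        with pytest.raises(ValueError, match="sham"):
            bonferroni_vs_sham(t[t["dose_gy"] > 0])

    def test_pooled_error_equals_anova_residual(self, rng):
        t = self.make_table(rng, doses=(0.0, 2.0, 10.0), tps=("t1", "t2"))
        res = two_way_anova(t)
        ms, df = pooled_error(t, ["dose_gy", "timepoint"], "value")
        assert ms == pytest.approx(res.residual_ms, rel=1e-10)
        assert df == res.residual_df

    def test_null_familywise_error_controlled(self):
        # quick version of the type-I check (the full 2000-rep run lives in
        # the acceptance suite)
        rng = np.random.default_rng(99)
        hits = 0
        reps = 300
        for _ in range(reps):
            t = self.make_table(rng, effect=0.0, n=3)
            out = bonferroni_vs_sham(t, family="all")
            hits += int((out["p_adj"] < 0.05).any())
        assert hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


def test_star_codes():
    assert star_code(0.0005) == "***"
    assert star_code(0.005) == "**"
    assert star_code(0.04) == "*"
    assert star_code(0.2) == "ns"
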