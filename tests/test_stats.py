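"""Participant z-scores, the 2x3 within-subject ANOVA, post-hocs, outliers."""

import numpy as np
import pandas as pd
import pytest

from handover.stats import (
    SIZE_LEVELS,
    WEIGHT_LEVELS,
    aggregate_cells,
    analyze_features,
    iqr_outliers,
    posthoc_weight,
    rm_anova_2way,
    zscore_by_participant,
)


def _cell_table(y):
    """Long cell table from an array y[participant, size, weight]."""
    rows = []
    for p in range(y.shape[0]):
        for i, s in enumerate(SIZE_LEVELS):
            for j, w in enumerate(WEIGHT_LEVELS):
                rows.append(
                    {"participant": f"P{p:02d}", "size": s, "weight": w, "y": y[p, i, j]}
                )
    return pd.DataFrame(rows)


class TestZscore:
    def test_three_values_standardize_by_hand(self):
        df = pd.DataFrame({"participant": ["P1"] * 3, "y": [1.0, 2.0, 3.0]})
        out = zscore_by_participant(df, "y")
        np.testing.assert_allclose(out["y"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self, rng):
        df = pd.DataFrame(
            {
                "participant": np.repeat(["P1", "P2"], 30),
                "y": rng.normal(size=60),
            }
        )
        once = zscore_by_participant(df, "y")
        twice = zscore_by_participant(once, "y")
        np.testing.assert_allclose(once["y"], twice["y"], atol=1e-12)

    def test_per_participant_mean_zero_sd_one(self, rng):
        df = pd.DataFrame(
            {
                "participant": np.repeat([f"P{i}" for i in range(5)], 24),
                "y": rng.normal(loc=rng.normal(0, 10, 120), scale=3),
            }
        )
        out = zscore_by_participant(df, "y")
        for _, grp in out.groupby("participant"):
            assert grp["y"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["y"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_values_rejected_naming_participant(self):
        df = pd.DataFrame({"participant": ["P7"] * 4, "y": [2.0] * 4})
        with pytest.raises(ValueError, match="P7"):
            zscore_by_participant(df, "y")


class TestAggregateCells:
    def test_ten_reps_reduce_to_six_cells(self, rng):
        rows = []
        for p in ("P1", "P2"):
            for s in SIZE_LEVELS:
                for w in WEIGHT_LEVELS:
                    for _ in range(10):
                        rows.append(
                            {"participant": p, "size": s, "weight": w, "y": rng.normal()}
                        )
        cells = aggregate_cells(pd.DataFrame(rows), "y")
        assert len(cells) == 12
        assert cells.groupby("participant").size().eq(6).all()

    def test_single_rep_is_identity(self, rng):
        y = rng.normal(size=(3, 2, 3))
        table = _cell_table(y)
        cells = aggregate_cells(table, "y")
        merged = table.merge(cells, on=["participant", "size", "weight"])
        np.testing.assert_allclose(merged["y_x"], merged["y_y"])

    def test_hand_computed_means(self):
        rows = []
        for p, base in (("P1", 0.0), ("P2", 10.0)):
            for s in SIZE_LEVELS:
                for w in WEIGHT_LEVELS:
                    rows += [
                        {"participant": p, "size": s, "weight": w, "y": base + 1.0},
                        {"participant": p, "size": s, "weight": w, "y": base + 3.0},
                    ]
        cells = aggregate_cells(pd.DataFrame(rows), "y")
        assert set(cells.loc[cells.participant == "P1", "y"]) == {2.0}
        assert set(cells.loc[cells.participant == "P2", "y"]) == {12.0}

    def test_empty_cell_rejected(self, rng):
        y = rng.normal(size=(2, 2, 3))
        table = _cell_table(y)
        table = table[
            ~((table.participant == "P01") & (table.weight == "heavy"))
        ]
        with pytest.raises(ValueError, match="empty"):
            aggregate_cells(table, "y")


def _anova_oracle(y):
    """From-scratch sums-of-squares oracle, written with explicit loops."""
    n, a, b = y.shape
    grand = y.mean()
    ss = {"subj": 0.0, "A": 0.0, "B": 0.0, "AB": 0.0, "As": 0.0, "Bs": 0.0}
    for s in range(n):
        ss["subj"] += a * b * (y[s].mean() - grand) ** 2
    for i in range(a):
        ss["A"] += n * b * (y[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (y[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["As"] += b * (
                y[s, i, :].mean() - y[:, i, :].mean() - y[s].mean() + grand
            ) ** 2
    for s in range(n):
        for j in range(b):
            ss["Bs"] += a * (
                y[s, :, j].mean() - y[:, :, j].mean() - y[s].mean() + grand
            ) ** 2
    ss_total = ((y - grand) ** 2).sum()
    ss["ABs"] = ss_total - sum(ss.values())
    f_a = (ss["A"] / (a - 1)) / (ss["As"] / ((a - 1) * (n - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["Bs"] / ((b - 1) * (n - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (
        ss["ABs"] / ((a - 1) * (b - 1) * (n - 1))
    )
    denom_extra = ss["subj"] + ss["As"] + ss["Bs"] + ss["ABs"]
    ges = {k: ss[k] / (ss[k] + denom_extra) for k in ("A", "B", "AB")}
    return (f_a, f_b, f_ab), ges


class TestRmAnova:
    def test_degrees_of_freedom_for_40_participants(self, rng):
        y = rng.normal(size=(40, 2, 3))
        res = rm_anova_2way(_cell_table(y), "y")
        assert (res.weight.df_num, res.weight.df_den) == (2, 78)
        assert (res.size.df_num, res.size.df_den) == (1, 39)
        assert (res.interaction.df_num, res.interaction.df_den) == (2, 78)

    def test_matches_sums_of_squares_oracle_on_random_designs(self, rng):
        """F statistics and ges match a loop-written oracle to 1e-9 on 200
        random small designs (3..6 participants)."""
        for _ in range(200):
            n = int(rng.integers(3, 7))
            y = rng.normal(size=(n, 2, 3)) + rng.normal(size=(n, 1, 1))
            res = rm_anova_2way(_cell_table(y), "y")
            (f_a, f_b, f_ab), ges = _anova_oracle(y)
            assert res.size.F == pytest.approx(f_a, abs=1e-9, rel=1e-9)
            assert res.weight.F == pytest.approx(f_b, abs=1e-9, rel=1e-9)
            assert res.interaction.F == pytest.approx(f_ab, abs=1e-9, rel=1e-9)
            assert res.size.ges == pytest.approx(ges["A"], abs=1e-9)
            assert res.weight.ges == pytest.approx(ges["B"], abs=1e-9)
            assert res.interaction.ges == pytest.approx(ges["AB"], abs=1e-9)

    def test_matches_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        for seed in range(5):
            y = np.random.default_rng(seed).normal(size=(8, 2, 3))
            table = _cell_table(y)
            res = rm_anova_2way(table, "y")
            aov = pg.rm_anova(
                data=table,
                dv="y",
                within=["size", "weight"],
                subject="participant",
                detailed=True,
                effsize="ng2",
            ).set_index("Source")
            assert res.size.F == pytest.approx(aov.loc["size", "F"])
            assert res.weight.F == pytest.approx(aov.loc["weight", "F"])
            assert res.interaction.F == pytest.approx(aov.loc["size * weight", "F"])
            assert res.size.p == pytest.approx(aov.loc["size", "p_unc"])
            assert res.weight.p == pytest.approx(aov.loc["weight", "p_unc"])
            assert res.size.ges == pytest.approx(aov.loc["size", "ng2"])
            assert res.weight.ges == pytest.approx(aov.loc["weight", "ng2"])

    def test_constant_response_flagged_degenerate(self):
        y = np.full((4, 2, 3), 2.5)
        res = rm_anova_2way(_cell_table(y), "y")
        assert res.weight.degenerate and np.isnan(res.weight.F)

    def test_too_few_participants_rejected(self, rng):
        y = rng.normal(size=(1, 2, 3))
        with pytest.raises(ValueError, match="2 participants"):
            rm_anova_2way(_cell_table(y), "y")


class TestPosthoc:
    def test_identical_conditions_null_result(self, rng):
        base = rng.normal(size=(5, 2, 1))
        y = np.repeat(base, 3, axis=2)
        res = posthoc_weight(_cell_table(y), "y")
        for _, row in res.comparisons.iterrows():
            assert row.t == 0.0 and row.cohens_d == 0.0

    def test_unit_sd_differences_give_d_of_two(self):
        """Medium - light differences {1, 2, 3}: mean 2, sd 1 -> d = 2."""
        y = np.zeros((3, 2, 3))
        y[:, :, 1] = np.array([1.0, 2.0, 3.0])[:, None]
        y[:, :, 2] = np.array([10.0, 12.0, 15.0])[:, None]
        res = posthoc_weight(_cell_table(y), "y")
        assert res[("light", "medium")].cohens_d == pytest.approx(2.0)

    def test_antisymmetric_under_order_reversal(self, rng):
        y = rng.normal(size=(6, 2, 3))
        res = posthoc_weight(_cell_table(y), "y")
        # reverse the weight labelling and check d flips sign
        flipped = y[:, :, ::-1]
        res_f = posthoc_weight(_cell_table(flipped), "y")
        assert res[("light", "heavy")].cohens_d == pytest.approx(
            -res_f[("light", "heavy")].cohens_d
        )


class TestIqrOutliers:
    def test_interpolated_quartile_fences(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        mask = iqr_outliers(values)
        assert mask.sum() == 1 and mask[-1]

    def test_all_equal_none_flagged(self):
        assert not iqr_outliers(np.full(10, 3.3)).any()

    def test_symmetric_data_symmetric_flags(self):
        v = np.array([-50, -1, -0.5, 0, 0.5, 1, 50], dtype=float)
        mask = iqr_outliers(v)
        np.testing.assert_array_equal(mask, mask[::-1])

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 4"):
            iqr_outliers(np.array([1.0, 2.0, 3.0]))


def test_outlier_exclusion_preserves_conclusions(experiment_20_dyads):
    """Re-running the ANOVA with 1.5-IQR outliers removed leaves the
    direction and significance pattern unchanged."""
    features, _ = experiment_20_dyads
    _, _, with_out = analyze_features(features)
    _, _, without = analyze_features(features, drop_outliers=True)
    for res in (with_out, without):
        assert res["lift_delay"].weight.p < 0.001
        assert res["max_lift_velocity"].weight.p < 0.001
        assert res["receiver_pgfr"].weight.p < 0.001
        assert res["giver_pgfr"].size.p < 0.05
        assert res["giver_pgfr"].weight.p > 0.05
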