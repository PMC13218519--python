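import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trivasc.datasets import LAYER_SUMMARIES, TOTAL_SUMMARIES
from trivasc.errors import DegenerateInputError, ValidationError
from trivasc.stats import (
    AggregationPlan,
    GroupSummary,
    aggregate,
    pearson_linreg,
    runs_pmf,
    runs_test,
    severity_measures,
    tukey_kramer,
    two_way_anova,
    two_way_anova_from_summary,
    welch_from_raw,
    welch_from_summary,
)


def exact_mean_sd_sample(n, mean, sd, rng=None):
    """Samples with exactly the requested mean and sample SD."""
    base = np.linspace(-1.0, 1.0, n)
    if rng is not None:
        base = rng.normal(size=n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


class TestAggregate:
    def frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["animal_id", "eccentricity_mm", "age_weeks", "value"],
        )

    def test_stacks_average_within_band(self):
        df = self.frame([["m1", "0-0.5", 30, 10.0], ["m1", "0-0.5", 30, 20.0]])
        per_band, per_animal = aggregate(df)
        assert per_band["value"].tolist() == [15.0]
        assert per_animal["value"].tolist() == [15.0]

    def test_animal_mean_over_bands(self):
        df = self.frame(
            [
                ["m1", "0-0.5", 30, 10.0],
                ["m1", "0.5-1.0", 30, 20.0],
                ["m1", "1.0-1.5", 30, 30.0],
                ["m1", "1.5-2.0", 30, 40.0],
            ]
        )
        _, per_animal = aggregate(df)
        assert per_animal["value"].tolist() == [25.0]

    def test_two_stage_mean_not_pooled(self):
        # m1: band A stacks (0, 10) -> 5; band B stack (30) -> 30;
        # animal mean (5 + 30)/2 = 17.5; the pooled mean would be 13.33
        df = self.frame(
            [
                ["m1", "0-0.5", 30, 0.0],
                ["m1", "0-0.5", 30, 10.0],
                ["m1", "0.5-1.0", 30, 30.0],
                ["m2", "0-0.5", 10, 8.0],
                ["m3", "0-0.5", 55, 1.0],
                ["m3", "0-0.5", 55, 3.0],
            ]
        )
        _, per_animal = aggregate(df)
        vals = dict(zip(per_animal["animal_id"], per_animal["value"]))
        assert vals == {"m1": 17.5, "m2": 8.0, "m3": 2.0}

    def test_age_bins_and_epochs(self):
        plan = AggregationPlan()
        assert [plan.age_bin(w) for w in (10, 25, 35, 45, 55)] == [
            "<20", "20-30", "30-40", "40-50", ">50",
        ]
        assert plan.age_epoch(30) == "young_adult"
        assert plan.age_epoch(31) == "middle_aged"

    def test_missing_key_rejected(self):
        df = self.frame([["m1", None, 30, 10.0]])
        with pytest.raises(ValidationError, match="eccentricity"):
            aggregate(df)


class TestWelch:
    def test_identical_groups(self):
        g = GroupSummary("x", 10, 5.0, 1.0)
        res = welch_from_summary(g, g)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_raw_equals_summary_exactly(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 2, 13), rng.normal(0.5, 1, 14)
        raw = welch_from_raw(x, y)
        summ = welch_from_summary(
            GroupSummary.from_samples("a", x), GroupSummary.from_samples("b", y)
        )
        assert raw.statistic == summ.statistic
        assert raw.p_value == summ.p_value

    def test_matches_scipy_from_stats(self):
        a = GroupSummary("e", 13, 80.92, 12.44)
        b = GroupSummary("h", 14, 78.91, 8.26)
        res = welch_from_summary(a, b)
        t, p = sps.ttest_ind_from_stats(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
        )
        assert res.statistic == pytest.approx(float(t), rel=1e-12)
        assert res.p_value == pytest.approx(float(p), rel=1e-12)

    @pytest.mark.parametrize(
        "metric,expected_p",
        [("vessel_density_mm_per_mm2", 0.629),
         ("mean_segment_length_um", 0.464)],
    )
    def test_worked_examples(self, metric, expected_p):
        e, h = TOTAL_SUMMARIES[metric]
        assert welch_from_summary(e, h).p_value == pytest.approx(
            expected_p, abs=0.01
        )

    def test_p_monotone_in_statistic(self):
        ps = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            res = welch_from_summary(
                GroupSummary("a", 13, 10.0 + shift, 2.0),
                GroupSummary("b", 14, 10.0, 2.5),
            )
            ps.append(res.p_value)
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_both_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            welch_from_summary(
                GroupSummary("a", 5, 1.0, 0.0), GroupSummary("b", 5, 2.0, 0.0)
            )


def random_cell_data(rng, unbalanced=True):
    rows = []
    for g in ("e", "h"):
        for lay in ("S", "I", "D"):
            n = int(rng.integers(4, 9)) if unbalanced else 6
            vals = rng.normal(
                10 + (g == "h") * 2 + {"S": 0, "I": 1, "D": 3}[lay], 2.0, n
            )
            rows += [{"group": g, "layer": lay, "value": v} for v in vals]
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_equal_cells_no_effects(self):
        rng = np.random.default_rng(0)
        base = exact_mean_sd_sample(8, 10.0, 2.0)
        rows = [
            {"group": g, "layer": lay, "value": v}
            for g in ("e", "h")
            for lay in ("S", "I")
            for v in base
        ]
        res = two_way_anova(pd.DataFrame(rows))
        for effect in ("group", "layer", "interaction"):
            assert res.table.loc[effect, "F"] == pytest.approx(0.0, abs=1e-20)

    def test_additive_means_zero_interaction(self):
        rows = []
        for g, ge in (("e", 0.0), ("h", 3.0)):
            for lay, le in (("S", 0.0), ("I", 5.0)):
                for v in exact_mean_sd_sample(7, 10 + ge + le, 1.5):
                    rows.append({"group": g, "layer": lay, "value": v})
        res = two_way_anova(pd.DataFrame(rows))
        assert res.table.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-18)
        assert res.table.loc["group", "p"] < 1e-3

    def test_summary_mode_equals_raw_mode(self):
        rng = np.random.default_rng(42)
        data = random_cell_data(rng)
        raw = two_way_anova(data)
        cells = (
            data.groupby(["group", "layer"])["value"]
            .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
            .reset_index()
        )
        summ = two_way_anova_from_summary(cells)
        for effect in ("group", "layer", "interaction"):
            assert summ.table.loc[effect, "F"] == pytest.approx(
                raw.table.loc[effect, "F"], rel=1e-9
            )
            assert summ.table.loc[effect, "SS"] == pytest.approx(
                raw.table.loc[effect, "SS"], rel=1e-9
            )
        assert summ.df_error == raw.df_error

    def test_summary_mode_against_reconstruction_oracle(self):
        """Summary-mode fit vs raw fit on samples reconstructed to match
        each cell's printed mean/SD exactly."""
        cells = pd.DataFrame(
            [
                {"group": g, "layer": lay, "n": n, "mean": m, "sd": s}
                for (g, lay, n, m, s) in [
                    ("e", "S", 13, 1.11, 0.03), ("e", "I", 13, 1.19, 0.02),
                    ("e", "D", 13, 1.17, 0.02), ("h", "S", 14, 1.11, 0.02),
                    ("h", "I", 14, 1.19, 0.04), ("h", "D", 14, 1.16, 0.02),
                ]
            ]
        )
        rows = []
        for _, c in cells.iterrows():
            for v in exact_mean_sd_sample(int(c["n"]), c["mean"], c["sd"]):
                rows.append({"group": c["group"], "layer": c["layer"], "value": v})
        raw = two_way_anova(pd.DataFrame(rows))
        summ = two_way_anova_from_summary(cells)
        for effect in ("group", "layer", "interaction"):
            assert summ.table.loc[effect, "F"] == pytest.approx(
                raw.table.loc[effect, "F"], rel=1e-6, abs=1e-9
            )

    def test_layer_by_group_tortuosity_interaction(self):
        """Glycemia x layer interaction from the worked-example tortuosity
        cells: F(4,125) near 2.635 (inputs carry 2-decimal rounding)."""
        cells = pd.DataFrame(
            [
                {"group": g.label, "layer": lay, "n": g.n,
                 "mean": g.mean, "sd": g.sd}
                for lay, pair in LAYER_SUMMARIES["mean_tortuosity"].items()
                for g in pair
            ]
        )
        res = two_way_anova_from_summary(cells)
        assert res.df_error == 125
        assert res.table.loc["interaction", "df"] == 4
        assert res.table.loc["interaction", "F"] == pytest.approx(2.635, abs=0.15)

    def test_empty_cell_rejected(self):
        data = random_cell_data(np.random.default_rng(1))
        data = data[~((data.group == "h") & (data.layer == "D"))]
        with pytest.raises(ValidationError, match="empty"):
            two_way_anova(data)


class TestTukeyKramer:
    def test_equal_means_p_one(self):
        rows = [
            {"group": g, "layer": "S", "value": v}
            for g in ("a", "b")
            for v in exact_mean_sd_sample(8, 5.0, 1.0)
        ]
        # need a second layer for a two-way fit; same values shifted
        rows += [
            {"group": g, "layer": "I", "value": v + 1}
            for g in ("a", "b")
            for v in exact_mean_sd_sample(8, 5.0, 1.0)
        ]
        res = two_way_anova(pd.DataFrame(rows))
        pairs = tukey_kramer(res)
        same = pairs[pairs.mean_diff.abs() < 1e-12]
        assert (same.q < 1e-9).all()
        assert (same.p_adj > 1.0 - 1e-9).all()

    @staticmethod
    def one_way_family(cells):
        """Wrap a one-way cell table as an AnovaResult for tukey_kramer."""
        from trivasc.stats import AnovaResult

        df_err = float((cells.n - 1).sum())
        ms_within = float(((cells.n - 1) * cells.sd**2).sum() / df_err)
        return AnovaResult(
            table=pd.DataFrame(), ms_within=ms_within, df_error=df_err,
            cells=cells, factors=("group", "layer"),
        )

    def test_k2_equals_pooled_t(self):
        """With exactly two balanced groups the studentized-range p equals
        the pooled-variance two-sample t p (q = t sqrt(2))."""
        rng = np.random.default_rng(9)
        x = rng.normal(10, 2, 12)
        y = rng.normal(11, 2, 12)
        cells = pd.DataFrame(
            {
                "group": ["a", "b"],
                "layer": ["all", "all"],
                "n": [12, 12],
                "mean": [x.mean(), y.mean()],
                "sd": [x.std(ddof=1), y.std(ddof=1)],
            }
        )
        pairs = tukey_kramer(self.one_way_family(cells))
        sp2 = ((12 - 1) * cells.sd[0] ** 2 + (12 - 1) * cells.sd[1] ** 2) / 22
        t = abs(x.mean() - y.mean()) / np.sqrt(sp2 * (2 / 12))
        p_pooled = 2 * sps.t.sf(t, 22)
        assert pairs.q[0] == pytest.approx(t * np.sqrt(2), rel=1e-12)
        assert pairs.p_adj[0] == pytest.approx(p_pooled, abs=1e-6)

    def test_k3_matches_monte_carlo_studentized_range(self):
        """Adjusted p for k=3 equal-n cells vs 10^6-draw Monte Carlo of
        the studentized range."""
        rng = np.random.default_rng(123)
        n, k = 6, 3
        cells = pd.DataFrame(
            {
                "group": ["g"] * k,
                "layer": ["S", "I", "D"],
                "n": [n] * k,
                "mean": [10.0, 11.0, 13.0],
                "sd": [1.5, 1.4, 1.6],
            }
        )
        family = self.one_way_family(cells)
        pairs = tukey_kramer(family)
        draws = 10**6
        z = rng.normal(size=(draws, k))
        s2 = rng.chisquare(family.df_error, size=draws) / family.df_error
        q_null = (z.max(axis=1) - z.min(axis=1)) / np.sqrt(s2)
        for _, row in pairs.iterrows():
            p_mc = float(np.mean(q_null > row.q))
            assert row.p_adj == pytest.approx(p_mc, abs=0.005)


class TestPearsonLinreg:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = pearson_linreg(x, 2 * x)
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(101)
        res = pearson_linreg(rng.normal(size=10**4), rng.normal(size=10**4))
        assert abs(res["r"]) < 0.05

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = pearson_linreg(x, y)
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2))
            * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert res["r"] == pytest.approx(r_direct, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_linreg(np.ones(5), np.arange(5.0))

    def test_constant_y_convention(self):
        with pytest.warns(UserWarning):
            res = pearson_linreg(np.arange(5.0), np.ones(5))
        assert res["r"] == 0.0


class TestRunsTest:
    def test_alternating_signs_extreme(self):
        res = runs_test(np.tile([1.0, -1.0], 10))
        assert res.statistic == 20
        assert res.p_value < 0.001

    def test_two_blocks_clustered_and_flagged(self):
        res = runs_test(np.concatenate([np.ones(10), -np.ones(10)]))
        assert res.statistic == 2
        assert res.p_value < 0.001
        assert "extreme_clustering" in res.flags

    def test_single_sign_degenerate(self):
        res = runs_test(np.ones(8))
        assert "single_sign" in res.flags
        assert res.p_value == 1.0

    def test_zeros_dropped_and_order_by_x(self):
        x = np.array([3.0, 1.0, 2.0, 4.0])
        res = runs_test(np.array([1.0, -1.0, 0.0, 1.0]), x=x)
        # ordered by x: -1, (0 dropped), 1, 1 -> 2 runs of n=3
        assert res.statistic == 2

    def test_pmf_sums_to_one(self):
        for n1, n2 in [(5, 5), (3, 9), (7, 13)]:
            total = sum(runs_pmf(r, n1, n2) for r in range(1, n1 + n2 + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_normal_approx_close_to_exact_when_balanced(self):
        """The continuity-corrected normal approximation stays within 0.03
        of exact enumeration for n <= 20: each one-sided tail with at
        least 6 of each sign, the (doubled) two-sided p with at least 7
        — the doubling doubles the tail error, so it needs one more of
        the rarer sign."""
        from trivasc.stats import _runs_approx_tails, _runs_exact_tails

        worst_tail, worst_two_sided = 0.0, 0.0
        for n1 in range(6, 15):
            for n2 in range(n1, 15):
                if n1 + n2 > 20:
                    continue
                for r in range(2, n1 + n2 + 1):
                    if runs_pmf(r, n1, n2) == 0:
                        continue
                    el, eh = _runs_exact_tails(r, n1, n2)
                    al, ah = _runs_approx_tails(r, n1, n2)
                    worst_tail = max(worst_tail, abs(el - al), abs(eh - ah))
                    if n1 >= 7:
                        worst_two_sided = max(
                            worst_two_sided,
                            abs(min(1, 2 * min(el, eh)) - min(1, 2 * min(al, ah))),
                        )
        assert worst_tail <= 0.03
        assert worst_two_sided <= 0.03


class TestSeverity:
    def test_flat_series(self):
        out = severity_measures([150, 150, 150])
        assert out == {"mean_bg_mg_dl": 150.0, "weeks_above_400": 0}

    def test_mixed_series(self):
        out = severity_measures([500, 450, 300])
        assert out["mean_bg_mg_dl"] == pytest.approx(416.67, abs=0.01)
        assert out["weeks_above_400"] == 2

    def test_exactly_400_not_counted(self):
        assert severity_measures([400.0, 401.0])["weeks_above_400"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            severity_measures([])
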