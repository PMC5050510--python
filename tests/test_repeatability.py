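import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from stressrep import (
    CortisolSimConfig,
    GroupSummary,
    assumption_checks,
    classify_responders,
    free_cortisol_metrics,
    nested_anova,
    pooled_t_from_raw,
    pooled_t_from_summary,
    repeatability_estimate,
    simulate_cortisol,
    two_way_rm_anova,
    variance_components,
)
from conftest import random_unbalanced_phenotypes


def brute_force_ss(data: pd.DataFrame):
    """Direct evaluation of the three nested sums of squares."""
    grand = data["cortisol"].mean()
    ss_fam = ss_ind = ss_within = 0.0
    for _, fam in data.groupby("family_id"):
        fam_mean = fam["cortisol"].mean()
        ss_fam += len(fam) * (fam_mean - grand) ** 2
        for _, ind in fam.groupby("fish_id"):
            ind_mean = ind["cortisol"].mean()
            ss_ind += len(ind) * (ind_mean - fam_mean) ** 2
            ss_within += ((ind["cortisol"] - ind_mean) ** 2).sum()
    return ss_fam, ss_ind, ss_within


class TestNestedAnova:
    def test_zero_within_variance_gives_infinite_f(self):
        rows = []
        for f, fam in enumerate(["A", "B"]):
            for i in range(2):
                value = float(1 + 2 * f + i)
                for occ in (1, 2):
                    rows.append({"fish_id": f"{fam}{i}", "family_id": fam,
                                 "occasion": occ, "cortisol": value})
        anova = nested_anova(pd.DataFrame(rows))
        assert anova.ss_within == 0
        assert math.isinf(anova.f_individual)
        est = repeatability_estimate(anova)
        assert est.r == pytest.approx(1.0)
        assert est.measurement_error == 0

    def test_df_structure_of_unbalanced_cohort(self):
        """6 families, 64 individuals, 193 observations -> df (5, 58, 129)."""
        rng = np.random.default_rng(42)
        fam_sizes = [11, 11, 11, 11, 10, 10]  # 64 fish over 6 families
        rows = []
        fish = 0
        n_obs_per_fish = [2] * 63 + [3]  # placeholder, fixed below
        # distribute 193 observations: 63 fish x 3 + 1 fish x 4 = 193
        counts = [3] * 63 + [4]
        for f, size in enumerate(fam_sizes):
            for _ in range(size):
                n = counts[fish]
                for occ in range(1, n + 1):
                    rows.append({"fish_id": f"fish{fish:02d}",
                                 "family_id": f"fam{f}", "occasion": occ,
                                 "cortisol": float(rng.gamma(4, 25))})
                fish += 1
        data = pd.DataFrame(rows)
        anova = nested_anova(data)
        assert anova.n_obs == 193
        assert (anova.df_family, anova.df_individual, anova.df_within) == (5, 58, 129)

    def test_ss_decomposition_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            data = random_unbalanced_phenotypes(rng)
            try:
                anova = nested_anova(data)
            except ValueError:
                continue  # degenerate draw (e.g. all singleton individuals)
            ss_fam, ss_ind, ss_within = brute_force_ss(data)
            assert anova.ss_family == pytest.approx(ss_fam, rel=1e-10)
            assert anova.ss_individual == pytest.approx(ss_ind, rel=1e-10)
            assert anova.ss_within == pytest.approx(ss_within, rel=1e-10)
            total = ((data["cortisol"] - data["cortisol"].mean()) ** 2).sum()
            assert (anova.ss_family + anova.ss_individual + anova.ss_within
                    == pytest.approx(total, rel=1e-8))
            assert (anova.df_family + anova.df_individual + anova.df_within
                    == len(data) - 1)

    def test_balanced_design_matches_closed_form(self):
        rng = np.random.default_rng(5)
        a, m, n = 4, 3, 5  # families, fish per family, replicates
        values = rng.normal(50, 10, size=(a, m, n))
        rows = [{"fish_id": f"f{i}_{j}", "family_id": f"fam{i}",
                 "occasion": t + 1, "cortisol": float(values[i, j, t])}
                for i in range(a) for j in range(m) for t in range(n)]
        anova = nested_anova(pd.DataFrame(rows))
        grand = values.mean()
        fam_means = values.mean(axis=(1, 2))
        ind_means = values.mean(axis=2)
        assert anova.ss_family == pytest.approx(
            n * m * ((fam_means - grand) ** 2).sum())
        assert anova.ss_individual == pytest.approx(
            n * ((ind_means - fam_means[:, None]) ** 2).sum())
        assert anova.ss_within == pytest.approx(
            ((values - ind_means[..., None]) ** 2).sum())
        est = repeatability_estimate(anova)
        assert est.n0 == pytest.approx(n)

    def test_degenerate_designs_rejected(self):
        single_family = pd.DataFrame({
            "fish_id": ["a", "a", "b", "b"], "family_id": ["f"] * 4,
            "occasion": [1, 2, 1, 2], "cortisol": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            nested_anova(single_family)
        singletons = pd.DataFrame({
            "fish_id": ["a", "b", "c", "d"],
            "family_id": ["f1", "f1", "f2", "f2"],
            "occasion": [1, 1, 1, 1], "cortisol": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            nested_anova(singletons)


class TestRepeatabilityEstimate:
    def test_equal_mean_squares_give_zero_r(self, default_cohort):
        anova = nested_anova(default_cohort)
        forced = dataclasses.replace(
            anova, ss_individual=anova.ms_within * anova.df_individual)
        est = repeatability_estimate(forced)
        assert est.r == pytest.approx(0.0)
        assert not est.negative_s2_among

    def test_negative_s2_among_flagged_not_clamped(self, default_cohort):
        anova = nested_anova(default_cohort)
        forced = dataclasses.replace(
            anova, ss_individual=0.5 * anova.ms_within * anova.df_individual)
        est = repeatability_estimate(forced)
        assert est.r < 0
        assert est.negative_s2_among

    def test_parameter_recovery_at_true_r_04(self):
        """Mean r-hat over seeded cohorts recovers the configured r = 0.4."""
        rs = []
        for seed in range(100):
            table = simulate_cortisol(
                CortisolSimConfig(seed=seed, missing_rate=0.0))
            rs.append(repeatability_estimate(
                nested_anova(table, response="z")).r)
        assert np.mean(rs) == pytest.approx(0.4, abs=0.05)

    def test_reduces_to_one_way_estimator_without_family_variance(self):
        """With var_family = 0 the nested estimator matches (in expectation)
        the one-way Lessells-Boag estimator that ignores family."""

        def one_way_lb(data):
            groups = data.groupby("fish_id")["cortisol"]
            n_i = groups.count().to_numpy(dtype=float)
            a = len(n_i)
            total = n_i.sum()
            grand = data["cortisol"].mean()
            means = groups.mean().to_numpy()
            ss_among = float((n_i * (means - grand) ** 2).sum())
            ss_within = float(((data["cortisol"]
                                - data.groupby("fish_id")["cortisol"]
                                .transform("mean")) ** 2).sum())
            ms_a = ss_among / (a - 1)
            ms_w = ss_within / (total - a)
            n0 = (total - (n_i ** 2).sum() / total) / (a - 1)
            s2a = (ms_a - ms_w) / n0
            return s2a / (s2a + ms_w)

        nested_rs, oneway_rs = [], []
        for seed in range(60):
            cfg = CortisolSimConfig(var_family=0.0, var_individual=3000.0,
                                    var_residual=4500.0,
                                    occasion_means=[300.0] * 4,
                                    missing_rate=0.0, seed=seed)
            table = simulate_cortisol(cfg)
            nested_rs.append(repeatability_estimate(nested_anova(table)).r)
            oneway_rs.append(one_way_lb(table))
        assert np.mean(nested_rs) == pytest.approx(np.mean(oneway_rs),
                                                   abs=0.02)

    def test_include_family_lowers_r(self, default_cohort):
        anova = nested_anova(default_cohort, response="raw")
        within_fam = repeatability_estimate(anova)
        cohort_wide = repeatability_estimate(anova, include_family=True)
        assert cohort_wide.r <= within_fam.r


class TestVarianceComponents:
    def test_single_family_inestimable(self):
        data = pd.DataFrame({
            "fish_id": ["a", "a", "b", "b"], "family_id": ["f"] * 4,
            "occasion": [1, 2, 1, 2], "cortisol": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            variance_components(data)

    def test_zero_family_variance_recovered_near_zero(self):
        pcts = []
        for seed in range(40):
            cfg = CortisolSimConfig(var_family=0.0, var_individual=3000.0,
                                    var_residual=4500.0, missing_rate=0.0,
                                    occasion_means=[300.0] * 4, seed=seed)
            pcts.append(variance_components(simulate_cortisol(cfg)).pct_family)
        assert np.mean(pcts) < 5.0

    def test_planted_components_recovered(self):
        cfg = CortisolSimConfig(
            n_families=30, n_per_family=20, n_occasions=4,
            var_family=0.3, var_individual=0.3, var_residual=0.4,
            occasion_means=[10.0] * 4, occasion_sd_scale=[1.0] * 4,
            missing_rate=0.0)
        est = []
        for seed in range(20):
            vc = variance_components(
                simulate_cortisol(dataclasses.replace(cfg, seed=seed)))
            est.append([vc.var_family, vc.var_individual, vc.var_residual])
        mean = np.mean(est, axis=0)
        assert mean == pytest.approx([0.3, 0.3, 0.4], rel=0.10)

    def test_pct_family_definition(self, default_cohort):
        vc = variance_components(default_cohort)
        total = vc.var_family + vc.var_individual + vc.var_residual
        assert vc.pct_family == pytest.approx(100 * vc.var_family / total)


class TestPooledT:
    def test_resting_cortisol_comparison(self):
        t, df, p = pooled_t_from_summary(GroupSummary(93.4, 63.4, 16),
                                         GroupSummary(203.3, 121.1, 16))
        assert abs(t) == pytest.approx(3.216, abs=5e-4)
        assert df == 30
        assert p == pytest.approx(0.003, abs=5e-4)

    def test_total_and_pct_free_cortisol_comparisons(self):
        t, df, _ = pooled_t_from_summary(GroupSummary(217.2, 58.6, 5),
                                         GroupSummary(439.2, 31.1, 5))
        assert abs(t) == pytest.approx(7.48, abs=5e-3)
        assert df == 8
        t, df, p = pooled_t_from_summary(GroupSummary(59.4, 13.4, 5),
                                         GroupSummary(61.8, 15.8, 5))
        assert abs(t) == pytest.approx(0.26, abs=5e-3)
        assert p == pytest.approx(0.80, abs=5e-3)

    def test_identical_summaries_give_zero_t(self):
        g = GroupSummary(10.0, 2.0, 8)
        t, df, p = pooled_t_from_summary(g, GroupSummary(10.0, 2.0, 8))
        assert (t, df, p) == (0.0, 14, pytest.approx(1.0))

    def test_zero_variance_conventions(self):
        t, _, p = pooled_t_from_summary(GroupSummary(5.0, 0.0, 4),
                                        GroupSummary(5.0, 0.0, 4))
        assert t == 0.0 and p == 1.0
        t, _, p = pooled_t_from_summary(GroupSummary(6.0, 0.0, 4),
                                        GroupSummary(5.0, 0.0, 4))
        assert math.isinf(t) and p == 0.0

    def test_raw_equals_summary(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(10, 3, rng.integers(3, 20))
            b = rng.normal(12, 4, rng.integers(3, 20))
            t_raw, df_raw, p_raw = pooled_t_from_raw(a, b)
            t_sum, df_sum, p_sum = pooled_t_from_summary(
                GroupSummary.from_values(a), GroupSummary.from_values(b))
            assert t_raw == pytest.approx(t_sum, abs=1e-10)
            assert df_raw == df_sum
            assert p_raw == pytest.approx(p_sum, abs=1e-10)

    def test_p_decreases_monotonically_in_shift(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 12)
        ps = [pooled_t_from_raw(base, base + shift)[2]
              for shift in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(ps[i] >= ps[i + 1] for i in range(len(ps) - 1))


class TestTwoWayRmAnova:
    @staticmethod
    def _cohort_with_group_effect(delta: float, seed: int):
        cfg = CortisolSimConfig(missing_rate=0.0, seed=seed)
        table = simulate_cortisol(cfg)
        labels = classify_responders(table)
        shift = table["fish_id"].map(
            labels.set_index("fish_id")["label"].map(
                {"HR": delta, "LR": 0.0, "INTERMEDIATE": 0.0}))
        table = table.assign(cortisol=table["cortisol"] + shift)
        return table, labels

    def test_planted_group_effect_detected(self):
        table, labels = self._cohort_with_group_effect(400.0, seed=21)
        res = two_way_rm_anova(table, labels).set_index("term")
        assert res.loc["group", "p"] < 1e-6
        assert res.loc["group", "F"] > res.loc["occasion", "F"]

    def test_matches_hand_computed_balanced_split_plot(self):
        table, labels = self._cohort_with_group_effect(100.0, seed=3)
        keep = labels[labels["label"].isin(["LR", "HR"])]
        df = table.merge(keep[["fish_id", "label"]], on="fish_id")
        wide = df.pivot_table(index=["fish_id", "label"], columns="occasion",
                              values="cortisol")
        y = wide.to_numpy()
        groups = wide.index.get_level_values("label").to_numpy()
        n_s, n_t = y.shape
        grand = y.mean()
        subj_means = y.mean(axis=1)
        group_means = {g: y[groups == g].mean() for g in ("LR", "HR")}
        occ_means = y.mean(axis=0)
        n_per = {g: (groups == g).sum() for g in ("LR", "HR")}
        ss_group = sum(n_per[g] * n_t * (group_means[g] - grand) ** 2
                       for g in ("LR", "HR"))
        ss_subj_within = sum(
            n_t * (subj_means[i] - group_means[groups[i]]) ** 2
            for i in range(n_s))
        f_group = (ss_group / 1) / (ss_subj_within / (n_s - 2))
        res = two_way_rm_anova(table, labels).set_index("term")
        assert res.loc["group", "F"] == pytest.approx(f_group, rel=1e-6)

    def test_incomplete_fish_dropped_and_small_groups_rejected(self):
        table, labels = self._cohort_with_group_effect(100.0, seed=4)
        incomplete = table[~((table["fish_id"] == table["fish_id"].iloc[0])
                             & (table["occasion"] == 1))]
        res = two_way_rm_anova(incomplete, labels)
        assert {"group", "occasion"} <= set(res["term"].str.split(" x ").str[0])
        tiny = labels.copy()
        tiny.loc[tiny["label"] == "HR", "label"] = "INTERMEDIATE"
        with pytest.raises(ValueError):
            two_way_rm_anova(table, tiny)


class TestAssumptionChecks:
    def test_constant_group_flagged(self):
        rng = np.random.default_rng(0)
        rep = assumption_checks({"a": [5.0, 5.0, 5.0],
                                 "b": rng.normal(0, 1, 10)})
        row = rep[(rep["check"] == "ks_normality") & (rep["group"] == "a")]
        assert row["note"].str.contains("constant").all()

    def test_ks_rejection_rate_near_alpha_for_normal_data(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            rep = assumption_checks({"g": rng.normal(3, 2, 100),
                                     "h": rng.normal(3, 2, 100)})
            p = rep.loc[rep["check"] == "ks_normality", "p"].iloc[0]
            rejections += p < 0.05
        assert 0.01 <= rejections / n_sims <= 0.11

    def test_levene_detects_tenfold_sd_ratio(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            rep = assumption_checks({"a": rng.normal(0, 1, 50),
                                     "b": rng.normal(0, 10, 50)})
            hits += rep.loc[rep["check"] == "levene", "p"].iloc[0] < 0.05
        assert hits / 40 >= 0.95


class TestFreeCortisol:
    def test_table_style_percentage(self):
        res = free_cortisol_metrics([217.2], [129.1])
        assert res["pct_free"].iloc[0] == pytest.approx(59.4, abs=0.05)

    def test_boundary_values(self):
        res = free_cortisol_metrics([100.0, 100.0], [0.0, 100.0])
        assert list(res["pct_free"]) == [0.0, 100.0]

    def test_zero_total_flagged_undefined(self):
        res = free_cortisol_metrics([0.0, 50.0], [0.0, 60.0])
        assert np.isnan(res["pct_free"].iloc[0])
        assert res["flag_zero_total"].iloc[0]
        assert res["flag_free_exceeds_total"].iloc[1]
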