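"""Layer derivations, group summaries and the classical group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from posthypoxia.simulate import SimConfig, simulate_oct_table
from posthypoxia.structstats import (
    GroupSummary,
    RetinalThicknessStudy,
    anova_tukey,
    anova_tukey_from_summary,
    derive_inl_to_rpe,
    group_delta,
    group_summary,
    paired_t,
    pearson_corr,
    two_way_anova,
)


class TestLayerDerivation:
    def test_printed_18h_means(self):
        assert derive_inl_to_rpe(229.1, 81.4) == pytest.approx(147.7)

    def test_printed_baseline_means_within_rounding(self):
        assert derive_inl_to_rpe(222.8, 79.13) == pytest.approx(143.6, abs=0.1)

    def test_small_gcc_limit(self):
        assert derive_inl_to_rpe(200.0, 1e-9) == pytest.approx(200.0)

    def test_gcc_at_least_trt_rejected(self):
        with pytest.raises(ValueError):
            derive_inl_to_rpe(80.0, 80.0)


class TestGroupSummary:
    def test_constant_values(self):
        s = group_summary([5, 5, 5])
        assert (s.mean, s.sem, s.n) == (5.0, 0.0, 3)

    def test_hand_computed_sem(self):
        s = group_summary([1, 2, 3, 4])
        assert s.mean == 2.5
        assert s.sem == pytest.approx(0.6455, abs=1e-4)  # SD = 1.2910

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestGroupDelta:
    @pytest.mark.parametrize(
        "a, b, delta, pct",
        [
            (218.5, 229.1, 10.6, 4.9),  # total retinal thickness, 18h vs 1h
            (77.0, 81.4, 4.4, 5.7),  # ganglion cell complex
        ],
    )
    def test_printed_table_arithmetic(self, a, b, delta, pct):
        d, p = group_delta(GroupSummary(a, 1.0, 8), GroupSummary(b, 1.0, 10))
        assert round(d, 1) == delta
        assert round(p, 1) == pct

    def test_identical_summaries(self):
        s = GroupSummary(10.0, 0.5, 4)
        assert group_delta(s, s) == (0.0, 0.0)


class TestPairedT:
    def test_textbook_hand_computation(self):
        # differences [2, 1, 3]: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.464
        res = paired_t([10, 12, 14], [12, 13, 17])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.t == pytest.approx(3.4641, abs=1e-4)
        assert res.p == pytest.approx(0.0742, abs=1e-3)
        assert res.df == 2

    def test_post_equals_pre(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_constant_shift_reported_as_degenerate_with_direction(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate
        assert "zero variance" in res.note
        assert res.mean_diff == 1.0
        assert res.t > 0

    def test_sign_convention_post_minus_pre(self):
        res = paired_t([5.0, 6.0, 9.0], [4.0, 5.0, 7.0])
        assert res.mean_diff < 0
        assert res.t < 0


class TestAnovaTukey:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = anova_tukey([g, g, g])
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert np.allclose(res.tukey["p"], 1.0)

    def test_hand_computed_three_groups(self):
        # groups [1,2,3], [2,3,4], [5,6,7]: SSB = 26, MSW = 1 -> F = 13
        res = anova_tukey([[1, 2, 3], [2, 3, 4], [5, 6, 7]],
                          labels=["g1", "g2", "g3"])
        assert res.F == pytest.approx(13.0)
        assert res.p == pytest.approx(stats.f.sf(13.0, 2, 6))

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1.0, size=n)
                  for loc, n in ((0.0, 5), (0.5, 7), (2.0, 4))]
        res = anova_tukey(groups)
        ref = stats.tukey_hsd(*groups)
        for row in res.tukey.itertuples():
            i = int(row.group_a[-1]) - 1
            j = int(row.group_b[-1]) - 1
            assert row.p == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_far_shifted_group_has_tiny_pairwise_p(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.01, size=5)
        res = anova_tukey([base, base + 0.02 * rng.normal(size=5), base + 50.0])
        far = res.tukey[(res.tukey["group_b"] == "group3")
                        | (res.tukey["group_a"] == "group3")]
        assert (far["p"] < 1e-3).all()


class TestAnovaFromSummary:
    def test_reproduces_raw_data_result(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc, 1.5, size=n)
                  for loc, n in ((0.0, 8), (1.0, 10), (0.4, 6))]
        raw = anova_tukey(groups)
        summ = anova_tukey_from_summary([group_summary(g) for g in groups])
        assert summ.F == pytest.approx(raw.F, rel=1e-10)
        assert summ.p == pytest.approx(raw.p, rel=1e-10)
        assert np.allclose(summ.tukey["p"], raw.tukey["p"], atol=1e-12)

    def test_printed_thickness_summaries_are_directionally_significant(self):
        # printed 1h and 18h group summaries plus a baseline group: the
        # 1h-vs-18h pairwise comparison must come out significant
        res = anova_tukey_from_summary(
            [GroupSummary(223.3, 2.6, 10), GroupSummary(218.5, 1.1, 8),
             GroupSummary(229.1, 0.7, 10)],
            labels=["baseline", "1h", "18h"],
        )
        pair = res.tukey[(res.tukey["group_a"] == "1h")
                         & (res.tukey["group_b"] == "18h")]
        assert float(pair["p"].iloc[0]) < 0.05

    def test_identical_summaries_give_p_one(self):
        s = GroupSummary(10.0, 1.0, 5)
        res = anova_tukey_from_summary([s, s])
        assert np.allclose(res.tukey["p"], 1.0)


class TestTwoWayAnova:
    @staticmethod
    def balanced_table(values):
        rows = []
        for (a, b), vals in values.items():
            for v in vals:
                rows.append({"layer": a, "group": b, "count": float(v)})
        return pd.DataFrame(rows)

    def test_hand_computed_balanced_design(self):
        # 2x2 with 2 replicates: SS_A=338, SS_B=98, SS_AB=18, SS_err=8
        # -> F_A=169, F_B=49, F_AB=9 on (1, 4) df
        table = self.balanced_table({
            ("L1", "g1"): (10, 12), ("L1", "g2"): (14, 16),
            ("L2", "g1"): (20, 22), ("L2", "g2"): (30, 32),
        })
        res = two_way_anova(table, "count", "layer", "group")
        assert res.loc["C(_a)", "F"] == pytest.approx(169.0)
        assert res.loc["C(_b)", "F"] == pytest.approx(49.0)
        assert res.loc["C(_a):C(_b)", "F"] == pytest.approx(9.0)

    def test_all_zero_counts_reported_degenerate(self):
        table = self.balanced_table({
            ("L1", "g1"): (0, 0), ("L1", "g2"): (0, 0),
            ("L2", "g1"): (0, 0), ("L2", "g2"): (0, 0),
        })
        res = two_way_anova(table, "count", "layer", "group")
        assert res["degenerate"].drop("Residual").all()
        assert (res["F"].drop("Residual") == 0).all()

    def test_additive_effects_have_zero_interaction(self):
        rng = np.random.default_rng(3)
        jitter = {k: rng.normal(0, 1e-9, 2) for k in range(4)}
        table = self.balanced_table({
            ("L1", "g1"): 10 + jitter[0], ("L1", "g2"): 12 + jitter[1],
            ("L2", "g1"): 15 + jitter[2], ("L2", "g2"): 17 + jitter[3],
        })
        res = two_way_anova(table, "count", "layer", "group")
        assert res.loc["C(_a):C(_b)", "F"] < 1.0

    def test_empty_cell_rejected(self):
        table = self.balanced_table({
            ("L1", "g1"): (1, 2), ("L1", "g2"): (3, 4), ("L2", "g1"): (5, 6),
        })
        with pytest.raises(ValueError, match="empty cells"):
            two_way_anova(table, "count", "layer", "group")


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_corr(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 5.0]
        r, _ = pearson_corr(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_simulated_thickness_coupling_recovered(self):
        # configured TRT-GCC correlation recovered across seeds
        rs = []
        for seed in range(150):
            table = simulate_oct_table(SimConfig(seed=seed, oct_coupling=0.85))
            base = table[table["timepoint"] == "baseline"]
            r, _ = pearson_corr(base["TRT"], base["GCC"])
            rs.append(r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        # mild attenuation from finite samples; 4 SE keeps the check honest
        assert abs(np.mean(rs) - 0.85) < 4 * se + 0.02


class TestThicknessStudy:
    def test_noise_free_study_recovers_configured_effects(self):
        cfg = SimConfig(oct_noise_sd=0.0)
        results = RetinalThicknessStudy(simulate_oct_table(cfg)).fit()
        t = results.layer_table.set_index(["group", "layer"])
        assert t.loc[("post1h", "TRT"), "delta"] == pytest.approx(-4.3)
        assert t.loc[("post18h", "TRT"), "delta"] == pytest.approx(5.8)
        assert t.loc[("post18h", "GCC"), "delta"] == pytest.approx(2.6)
        # layer conservation propagates to the derived layer's delta
        assert t.loc[("post18h", "INL_to_RPE"), "delta"] == pytest.approx(5.8 - 2.6)

    def test_summary_renders(self):
        results = RetinalThicknessStudy(simulate_oct_table(SimConfig(seed=1))).fit()
        text = results.summary()
        assert "paired p" in text
        assert "Tukey" in text
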