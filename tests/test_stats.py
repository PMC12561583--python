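import math

import numpy as np
import pytest
from scipy import stats as sps

import crpcoord as cc
from crpcoord.errors import ValidationError


class TestIndependentT:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = cc.independent_t(g, g)
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert res.effect_size == 0.0

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 30))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 30))
            ours = cc.independent_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
            welch = cc.independent_t(a, b, "welch")
            ref_w = sps.ttest_ind(a, b, equal_var=False)
            assert welch.statistic == pytest.approx(ref_w.statistic, abs=1e-10)
            assert welch.p == pytest.approx(ref_w.pvalue, abs=1e-10)

    def test_zero_variance_flags(self):
        res = cc.independent_t([1.0, 1.0], [2.0, 2.0])
        assert res.infinite
        assert res.p == 0.0
        equal = cc.independent_t([1.0, 1.0], [1.0, 1.0])
        assert equal.statistic == 0.0 and equal.p == 1.0

    def test_auto_levene_switches_to_welch(self, rng):
        a = rng.normal(0, 0.1, 20)
        b = rng.normal(0, 10.0, 20)
        auto = cc.independent_t(a, b, "auto_levene")
        welch = cc.independent_t(a, b, "welch")
        assert auto.df == pytest.approx(welch.df)

    def test_n_too_small(self):
        with pytest.raises(ValidationError):
            cc.independent_t([1.0], [2.0, 3.0])


class TestSummaryStatT:
    def test_equal_means_zero(self):
        assert cc.summary_stat_t(5.0, 1.0, 7, 5.0, 2.0, 7).statistic == 0.0

    def test_printed_table_summaries_reproduce_reported_t(self):
        # group means 1.79 (0.55) and 1.62 (0.46), n = 7 each: reported
        # t(12) = 0.64; recomputation from the rounded summaries gives 0.63
        res = cc.summary_stat_t(1.79, 0.55, 7, 1.62, 0.46, 7)
        assert res.df == 12
        assert res.statistic == pytest.approx(0.6273, abs=5e-4)
        assert abs(res.statistic - 0.64) <= 0.02
        assert res.p == pytest.approx(0.53, abs=0.02)

    def test_consistent_with_raw_data_t(self, rng):
        a = rng.normal(1.0, 2.0, 12)
        b = rng.normal(0.5, 1.5, 9)
        raw = cc.independent_t(a, b)
        summ = cc.summary_stat_t(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-12)
        assert summ.p == pytest.approx(raw.p, abs=1e-12)

    def test_matches_scipy_from_stats(self, rng):
        for _ in range(20):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.5, 3, 2)
            n1, n2 = rng.integers(3, 30, 2)
            ours = cc.summary_stat_t(m1, s1, int(n1), m2, s2, int(n2))
            ref = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestPairedT:
    def test_no_change(self):
        g = [1.0, 2.0, 3.0]
        res = cc.paired_t(g, g)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_differences(self):
        # differences {1,1,1,2}: mean 1.25, sd 0.5 -> t = 1.25/(0.5/2) = 5, df 3
        res = cc.paired_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 2.0])
        assert res.statistic == pytest.approx(5.0, abs=1e-12)
        assert res.df == 3

    def test_matches_scipy(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 25))
            a = rng.normal(size=n)
            b = a + rng.normal(0.3, 1.0, n)
            ours = cc.paired_t(a, b)
            ref = sps.ttest_rel(b, a)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_training_effect_power(self):
        """A 20-degree post-training shift at the preset effect size is
        detected by the paired t-test in nearly all replicates."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            sim = cc.study_preset(seed=seed, trials_per_subject=3,
                                  samples_per_cycle=64)
            ds = cc.simulate_cohort(sim)
            ms = cc.compute_subject_metrics(ds.trials, cc.AnalysisConfig())
            pre = {m.subject_id: m.marp for m in ms
                   if m.group == "control" and m.stage == "pre"
                   and m.coupling == ("ankle", "knee")}
            post = {m.subject_id: m.marp for m in ms
                    if m.group == "control" and m.stage == "post"
                    and m.coupling == ("ankle", "knee")}
            subjects = sorted(pre)
            res = cc.paired_t([pre[s] for s in subjects], [post[s] for s in subjects])
            hits += res.p < 0.05
        assert hits >= 0.8 * n_seeds

    def test_zero_variance_nonzero_shift_flagged(self):
        res = cc.paired_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.infinite


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = cc.one_way_anova([g, g, g])
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 11)
        f = cc.one_way_anova([a, b])
        t = cc.independent_t(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, abs=1e-9)
        assert f.p == pytest.approx(t.p, abs=1e-9)

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 20))
                      for _ in range(3)]
            ours = cc.one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert 0.0 <= ours.effect_size <= 1.0

    def test_df_pattern(self, rng):
        groups = [rng.normal(size=7), rng.normal(size=7), rng.normal(size=14)]
        res = cc.one_way_anova(groups)
        assert res.df == (2.0, 25.0)


class TestPosthoc:
    def test_df_pattern_7_7_14(self, rng):
        groups = {
            "control": rng.normal(size=7),
            "test": rng.normal(size=7),
            "target": rng.normal(size=14),
        }
        table = cc.posthoc_pairwise(groups)
        assert table[("control", "test")].df == 12
        assert table[("control", "target")].df == 19
        assert table[("test", "target")].df == 19

    def test_bonferroni_multiplies_and_caps(self, rng):
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(2, 1, 10),
                  "c": rng.normal(0, 1, 10)}
        raw = cc.posthoc_pairwise(groups, "none")
        adj = cc.posthoc_pairwise(groups, "bonferroni")
        for pair in [("a", "b"), ("a", "c"), ("b", "c")]:
            assert adj[pair].p == pytest.approx(min(1.0, raw[pair].p * 3), abs=1e-12)

    def test_symmetric(self, rng):
        groups = {"a": rng.normal(size=5), "b": rng.normal(size=6)}
        table = cc.posthoc_pairwise(groups)
        assert table[("a", "b")] is table[("b", "a")]


class TestAssumptionGate:
    def test_null_levene_rarely_rejects(self):
        rejections = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            rep = cc.assumption_gate(
                {"a": r.normal(0, 1, 30), "b": r.normal(0, 1, 30)}, alpha=0.05
            )
            rejections += not rep.levene[2]
        assert rejections <= 10

    def test_heavy_tails_rejected_by_shapiro(self):
        flagged = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            rep = cc.assumption_gate({"a": r.standard_cauchy(50)}, alpha=0.05)
            flagged += not rep.shapiro["a"][2]
        assert flagged >= 0.95 * 40

    def test_constant_sample_is_assumption_failure(self):
        rep = cc.assumption_gate({"a": np.ones(10), "b": np.random.default_rng(0).normal(size=10)})
        assert rep.shapiro["a"][2] is False
        assert not rep.all_passed

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            cc.assumption_gate({"a": [1.0, 2.0]})

    def test_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 2, 25)
        rep = cc.assumption_gate({"a": a, "b": b})
        w_ref, p_ref = sps.shapiro(a)
        assert rep.shapiro["a"][0] == pytest.approx(w_ref, abs=1e-12)
        lev_ref = sps.levene(a, b, center="mean")
        assert rep.levene[0] == pytest.approx(lev_ref.statistic, abs=1e-12)


class TestEffectSizes:
    def test_cohens_d_zero_iff_equal_means(self, rng):
        a = rng.normal(size=20)
        assert cc.cohens_d(a, a) == pytest.approx(0.0, abs=1e-12)
        assert cc.cohens_d(a, a + 1.0) != 0.0

    def test_dz_definition(self):
        res = cc.paired_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 2.0])
        assert res.effect_size == pytest.approx(1.25 / 0.5, abs=1e-12)
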