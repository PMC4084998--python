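import itertools
import math

import numpy as np
import pytest
from scipy import stats

from fpscan.comparative import (bonferroni_cutoff, kruskal_grouping,
                                mean_length_ogt, ogt_dependence, pearson_with_p,
                                spearman_with_p, study_hypothesis_count,
                                summarize_pairs)
from fpscan.peaks import PeakCall


def make_call(org, x="C", y="C", L=3, q=1.0, z=5.0, direction="N",
              significant=True):
    sign = "over" if q > 0 else "under"
    return PeakCall(organism_id=org, x=x, y=y, direction=direction, L=L,
                    observed=100, expected=100 * math.exp(-q), q=q, z=z,
                    significant=significant, sign=sign)


class TestPearson:
    def test_perfect_linearity(self):
        a = np.array([1.0, 2, 3, 4])
        res = pearson_with_p(a, 2 * a + 1)
        assert res.value == pytest.approx(1.0)
        assert res.method_p == "t_transform"

    def test_hand_computed_value(self):
        # r(( 1,2,3 ), ( 1,3,2 )) = 0.5 by direct covariance arithmetic
        res = pearson_with_p([1, 2, 3], [1, 3, 2])
        assert res.value == pytest.approx(0.5)

    def test_p_matches_t_transform_closed_form(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(size=30)
        res = pearson_with_p(a, b)
        t = res.value * math.sqrt((res.n - 2) / (1 - res.value ** 2))
        p = 2 * stats.t.sf(abs(t), res.n - 2)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = [pearson_with_p(rng.normal(size=200), rng.normal(size=200)).p_value
              for _ in range(200)]
        # KS against uniform should not reject at alpha = 0.001
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestSpearman:
    def test_monotone_gives_one(self):
        res = spearman_with_p([1, 2, 3, 5, 8], [2, 4, 9, 10, 30])
        assert res.value == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        res = spearman_with_p([1, 2, 3], [3, 2, 1])
        assert res.value == pytest.approx(-1.0)

    def test_exact_enumeration_matches_independent_oracle(self):
        a = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        b = [2.0, 7.0, 1.0, 8.0, 2.8, 1.9]
        res = spearman_with_p(a, b)
        assert res.method_p == "permutation_exact"
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        rho_obs = np.corrcoef(ra, rb)[0, 1]
        hits = sum(abs(np.corrcoef(ra, np.asarray(perm))[0, 1]) >= abs(rho_obs) - 1e-12
                   for perm in itertools.permutations(rb))
        assert res.p_value == pytest.approx(hits / math.factorial(6))

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=7), rng.normal(size=7)
        exact = spearman_with_p(a, b)
        # force the Monte-Carlo path by padding beyond the enumeration cap
        a9 = np.concatenate([a, rng.normal(size=2)])
        b9 = np.concatenate([b, rng.normal(size=2)])
        mc = spearman_with_p(a9, b9, n_perm=200_000, seed=5)
        ref = stats.spearmanr(a9, b9)
        assert mc.method_p == "permutation"
        assert mc.value == pytest.approx(ref.statistic, abs=1e-12)
        assert exact.method_p == "permutation_exact"

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=20), rng.normal(size=20)
        r1 = spearman_with_p(a, b, n_perm=5000, seed=42)
        r2 = spearman_with_p(a, b, n_perm=5000, seed=42)
        assert r1 == r2

    def test_ties_use_midranks(self):
        res = spearman_with_p([1, 2, 2, 3], [1, 2, 3, 4])
        assert res.value == pytest.approx(stats.spearmanr([1, 2, 2, 3],
                                                          [1, 2, 3, 4]).statistic)


class TestSummarizePairs:
    def test_recurrent_peak_retained_and_threshold_boundary(self):
        calls = [make_call(f"org{i}") for i in range(30)]
        kept = summarize_pairs(calls, min_genomes=30, qbar_scope="significant")
        assert len(kept) == 1
        s = kept[0]
        assert (s.x, s.y, s.L, s.n_genomes, s.sign) == ("C", "C", 3, 30, "over")
        assert s.q_bar == pytest.approx(1.0)
        assert summarize_pairs(calls, min_genomes=31,
                               qbar_scope="significant") == []

    def test_organism_order_invariance(self):
        calls = [make_call(f"org{i}", q=0.5 + 0.01 * i) for i in range(28)]
        fwd = summarize_pairs(calls, min_genomes=25, qbar_scope="significant")
        rev = summarize_pairs(calls[::-1], min_genomes=25, qbar_scope="significant")
        assert fwd == rev

    def test_modal_l_majority_with_tie_toward_smaller(self):
        calls = [make_call(f"a{i}", L=4) for i in range(25)]
        calls += [make_call(f"b{i}", L=2) for i in range(25)]
        s = summarize_pairs(calls, min_genomes=25, qbar_scope="significant")
        assert len(s) == 1 and s[0].L == 2

    def test_over_and_under_reported_separately(self):
        calls = [make_call(f"o{i}", q=1.0) for i in range(25)]
        calls += [make_call(f"u{i}", x="G", y="D", L=2, q=-0.2, z=-4.0)
                  for i in range(25)]
        out = summarize_pairs(calls, min_genomes=25, qbar_scope="significant")
        assert {s.sign for s in out} == {"over", "under"}

    def test_all_scope_requires_scores(self):
        with pytest.raises(ValueError):
            summarize_pairs([make_call("a")], qbar_scope="all")


class TestOgtDependence:
    def test_undefined_below_three_organisms(self):
        assert ogt_dependence([1.0, 2.0], [10.0, 20.0]) is None
        assert ogt_dependence([1.0, np.nan, 2.0], [10.0, 20.0, 30.0]) is None

    def test_recovers_linear_trend(self):
        rng = np.random.default_rng(8)
        ogt = np.linspace(5, 100, 40)
        q = 0.01 * ogt + rng.normal(scale=0.05, size=40)
        pe, sp = ogt_dependence(q, ogt, n_perm=20_000, seed=1)
        assert pe.value > 0.9 and sp.value > 0.9
        assert pe.p_value < 1e-6 and sp.p_value < 1e-3

    def test_mean_length_trend_sign_convention(self):
        # target more abundant at high OGT -> shorter passages -> rho < 0
        rng = np.random.default_rng(9)
        ogt = np.linspace(5, 100, 30)
        mean_L = 50 - 0.2 * ogt + rng.normal(scale=1.0, size=30)
        res = mean_length_ogt(mean_L, ogt, n_perm=10_000, seed=2)
        assert res.value < -0.5
        rising = mean_length_ogt(100 - mean_L, ogt, n_perm=10_000, seed=2)
        assert rising.value > 0.5


class TestKruskalGrouping:
    def test_all_equal_has_no_group_effect(self):
        m = np.full((20, 20), 7.0)
        res = kruskal_grouping(m)
        assert res.h_by_target == pytest.approx(0.0)
        assert res.p_by_target == pytest.approx(1.0)
        assert res.p_by_anchor == pytest.approx(1.0)

    def test_target_effect_detected_only_by_target(self):
        rng = np.random.default_rng(12)
        g = rng.uniform(10, 60, size=20)            # one level per target
        m = np.tile(g, (20, 1)) + rng.normal(scale=0.01, size=(20, 20))
        res = kruskal_grouping(m)
        assert res.p_by_target < 1e-10
        assert res.p_by_anchor > 0.05

    def test_h_matches_textbook_formula(self):
        groups = [np.array([1.0, 2, 5]), np.array([3.0, 4, 7]),
                  np.array([6.0, 8, 9])]
        all_vals = np.concatenate(groups)
        ranks = stats.rankdata(all_vals)
        n = all_vals.size
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start:start + g.size]
            h += g.size * (r.mean() - (n + 1) / 2) ** 2
            start += g.size
        h *= 12 / (n * (n + 1))
        m = np.full((20, 20), np.nan)
        m[0, :3], m[1, :3], m[2, :3] = groups
        res = kruskal_grouping(m.T)  # columns 0..2 hold the three groups
        assert res.h_by_target == pytest.approx(h)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            kruskal_grouping(np.ones((5, 5)))


class TestBonferroni:
    def test_published_study_cutoff(self):
        assert bonferroni_cutoff(0.05, 30400) == pytest.approx(13.318, abs=5e-4)

    def test_study_design_hypothesis_count(self):
        assert study_hypothesis_count(76) == 30400

    def test_no_correction_and_boundary(self):
        assert bonferroni_cutoff(0.05, 1) == pytest.approx(-math.log(0.05))
        assert bonferroni_cutoff(1.0, 1) == pytest.approx(0.0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_cutoff(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_cutoff(1.5, 10)
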