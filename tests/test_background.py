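import math

import numpy as np
import pytest

from fpscan.background import (fit_all_pairs, fit_background, frequency_table,
                               geometric_null, mean_first_passage)
from fpscan.first_passage import FirstPassageTable, count_all_pairs, \
    count_first_passages
from fpscan.proteome_io import OrganismRecord, Proteome
from fpscan.synthetic import SyntheticSpec, PlantedEffect, generate_proteome


def table_from_counts(counts, x="A", y="C", direction="C"):
    n = sum(counts.values())
    return FirstPassageTable(x=x, y=y, direction=direction, counts=counts,
                             n_anchors=n, n_censored=0)


def iid_proteome(f_y, n_residues, seed=0, target="C"):
    """Two-letter iid proteome: `target` at frequency f_y, A otherwise."""
    freqs = np.full(20, 0.0)
    ai, ci = "ACDEFGHIKLMNPQRSTVWY".index("A"), "ACDEFGHIKLMNPQRSTVWY".index(target)
    freqs[ai] = 1 - f_y
    freqs[ci] = f_y
    spec = SyntheticSpec(n_proteins=max(1, n_residues // 2000), length_mode="fixed",
                         mean_length=2000, min_length=2000,
                         base_frequencies=freqs + 1e-12, seed=seed)
    # tiny jitter keeps validation happy; renormalized internally
    return generate_proteome(spec)


class TestFitBackground:
    def test_recovers_exact_geometric_decay(self):
        counts = {L: int(round(1000 * 0.5 ** L * 2 ** 40)) for L in range(1, 41)}
        fit = fit_background(table_from_counts(counts), l_min=2, l_max=40)
        assert fit.valid
        assert fit.lam == pytest.approx(math.log(2), abs=1e-6)
        assert fit.resid_sd < 1e-6
        assert fit.r == pytest.approx(-1.0, abs=1e-9)

    def test_flat_counts_give_zero_decay(self):
        fit = fit_background(table_from_counts({L: 500 for L in range(1, 41)}),
                             l_min=2, l_max=40)
        assert fit.lam == pytest.approx(0.0, abs=1e-12)

    def test_too_few_bins_flags_failure_not_exception(self):
        fit = fit_background(table_from_counts({2: 10, 3: 8}))
        assert not fit.valid and fit.n_points < 3

    def test_window_outside_bounds_rejected(self):
        t = table_from_counts({L: 10 for L in range(1, 30)})
        with pytest.raises(ValueError):
            fit_background(t, l_min=0, l_max=40)
        with pytest.raises(ValueError):
            fit_background(t, l_min=2, l_max=50)

    def test_iid_simulation_matches_closed_form(self):
        f_y = 0.10
        p = iid_proteome(f_y, 400_000, seed=7)
        t = count_first_passages(p, "A", "C", "C")
        fit = fit_background(t)
        lam_true = -math.log(1 - f_y)
        assert fit.lam == pytest.approx(lam_true, rel=0.05)

    def test_directions_agree_on_iid_input(self):
        p = iid_proteome(0.10, 300_000, seed=11)
        lam = {}
        for d in ("N", "C"):
            lam[d] = fit_background(count_first_passages(p, "A", "C", d)).lam
        assert lam["N"] == pytest.approx(lam["C"], rel=0.05)

    def test_clipping_keeps_planted_peak_out_of_fit(self):
        spec = SyntheticSpec(n_proteins=200, length_mode="fixed", mean_length=2000,
                             min_length=2000, seed=3,
                             base_frequencies=np.full(20, 0.05),
                             planted_effects=[PlantedEffect("A", "C", 3, 0.5)])
        t = count_first_passages(generate_proteome(spec), "A", "C", "C")
        clipped = fit_background(t, clip_sigma=3.0)
        # oracle: plain OLS on ln(count) with the peak bin excluded by hand
        Ls = np.array([L for L in range(2, 50) if L != 3 and t.counts.get(L, 0) > 0])
        slope, _ = np.polyfit(Ls, np.log([t.counts[L] for L in Ls]), 1)
        assert clipped.lam == pytest.approx(-slope, rel=0.02)
        # the peak bin was dropped by the clipping pass
        unclipped = fit_background(t, clip_sigma=1e9)
        assert clipped.n_points < unclipped.n_points

    def test_linearity_pvalue_extreme_on_iid_data(self):
        p = iid_proteome(0.10, 300_000, seed=5)
        fit = fit_background(count_first_passages(p, "A", "C", "C"))
        assert -math.log(fit.p_linearity) > 13.318  # beyond any Bonferroni bar


class TestBatchFits:
    def test_matches_per_table_fits(self, rng, make_random_proteome):
        p = make_random_proteome(rng, n_chains=40, max_len=400, min_len=100)
        pc = count_all_pairs(p, "C")
        fits = fit_all_pairs(pc)
        for x, y in [("A", "C"), ("L", "L"), ("G", "D"), ("W", "W")]:
            single = fit_background(pc.table(x, y))
            batch = fits.fit(x, y)
            assert batch.valid == single.valid
            if single.valid:
                assert batch.lam == pytest.approx(single.lam, abs=1e-12)
                assert batch.resid_sd == pytest.approx(single.resid_sd, abs=1e-12)
                assert batch.p_linearity == pytest.approx(single.p_linearity,
                                                          rel=1e-9)


class TestGeometricNull:
    def test_closed_form(self):
        fit = fit_background(table_from_counts(
            {L: int(round(1000 * 0.5 ** L * 2 ** 40)) for L in range(1, 41)}),
            l_min=2, l_max=40)
        null = geometric_null(0.5, fit)
        assert null.lam_geo == pytest.approx(math.log(2))
        assert null.decay_length_geo == pytest.approx(1 / math.log(2))
        assert null.ratio == pytest.approx(1.0, abs=1e-5)

    def test_frequency_bounds_enforced(self):
        fit = fit_background(table_from_counts({L: 10 for L in range(1, 30)}))
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                geometric_null(bad, fit)

    def test_ratio_near_one_on_iid_proteome(self):
        f_y = 0.10
        p = iid_proteome(f_y, 400_000, seed=13)
        fit = fit_background(count_first_passages(p, "A", "C", "C"))
        null = geometric_null(f_y, fit)
        assert 0.95 <= null.ratio <= 1.05

    def test_nonpositive_lambda_flags_ratio_undefined(self):
        flat = fit_background(table_from_counts({L: 500 for L in range(1, 41)}),
                              l_min=2, l_max=40)
        null = geometric_null(0.3, flat)
        assert not null.ratio_defined and math.isnan(null.ratio)


class TestMeanFirstPassage:
    def test_half_probability_gives_mean_two(self):
        fit = fit_background(table_from_counts(
            {L: int(round(1000 * 0.5 ** L * 2 ** 40)) for L in range(1, 41)}),
            l_min=2, l_max=40)
        assert mean_first_passage(fit).mean_L == pytest.approx(2.0, abs=1e-5)

    def test_large_decay_limit_is_one(self):
        from fpscan.background import BackgroundFit
        fit = BackgroundFit("A", "C", "C", lam=10.0, intercept=0.0, resid_sd=0.0,
                            n_points=10, valid=True)
        assert mean_first_passage(fit).mean_L == pytest.approx(1.0, abs=1e-4)

    def test_iid_mean_matches_one_over_frequency(self):
        f_y = 0.05
        p = iid_proteome(f_y, 600_000, seed=17)
        fit = fit_background(count_first_passages(p, "A", "C", "C"))
        assert mean_first_passage(fit).mean_L == pytest.approx(1 / f_y, rel=0.05)

    def test_undefined_for_flat_background(self):
        flat = fit_background(table_from_counts({L: 500 for L in range(1, 41)}),
                              l_min=2, l_max=40)
        m = mean_first_passage(flat)
        assert not m.defined and math.isnan(m.mean_L)


class TestFrequencyTable:
    def test_small_example(self):
        p = Proteome(OrganismRecord("t"), chains=["AAC"])
        f = frequency_table(p)
        assert f["A"] == pytest.approx(2 / 3)
        assert f["C"] == pytest.approx(1 / 3)

    def test_sums_to_one_and_uniform_converges(self, rng, make_random_proteome):
        p = make_random_proteome(rng, n_chains=30, max_len=2000, min_len=2000)
        f = frequency_table(p)
        assert sum(f.values()) == pytest.approx(1.0)
        assert all(abs(v - 0.05) < 0.01 for v in f.values())
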