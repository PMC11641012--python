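"""Binding fits, multiple-comparison statistics, recombination arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from synaptrap.simulate import simulate_emsa
from synaptrap.stats import (
    BindingSeries,
    GroupSample,
    bound_fraction,
    compare_groups,
    fit_hill,
    group_summary,
    hill_curve,
    holm_adjust,
    recombination_frequency,
    stability_efficiency_correlation,
)


class TestBoundFraction:
    @pytest.mark.parametrize("ib,iu,expected", [
        (0.0, 5.0, 0.0),
        (5.0, 5.0, 0.5),
        (3.0, 1.0, 0.75),
    ])
    def test_values(self, ib, iu, expected):
        assert bound_fraction(ib, iu) == pytest.approx(expected)

    def test_zero_total_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            b = bound_fraction(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isnan(b[0]) and b[1] == 0.5

    def test_always_in_unit_interval(self, rng):
        ib = rng.uniform(0, 100, 500)
        iu = rng.uniform(0.01, 100, 500)
        b = bound_fraction(ib, iu)
        assert np.all((b >= 0) & (b <= 1))


class TestHillCurve:
    def test_half_saturation(self):
        assert hill_curve(150.0, 150.0, 0.9) == pytest.approx(0.45)

    def test_saturation_limit(self):
        assert hill_curve(1e9, 150.0, 0.9) == pytest.approx(0.9, abs=1e-6)

    def test_half_c_gives_bmax_over_17(self):
        # (1 + 2^4)^-1 = 1/17
        assert hill_curve(75.0, 150.0, 0.9) == pytest.approx(0.9 / 17.0)

    def test_monotone_increasing(self):
        c = np.linspace(1.0, 1000.0, 200)
        b = hill_curve(c, 150.0, 0.9)
        assert np.all(np.diff(b) > 0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_curve(0.0, 150.0, 0.9)


class TestFitHill:
    CONC = [10, 25, 50, 100, 150, 200, 400, 640]

    def test_noiseless_exact_recovery(self):
        s = simulate_emsa(150.0, 0.9, self.CONC, 0.0,
                          np.random.default_rng(0))
        fit = fit_hill(s)
        assert fit.success
        assert fit.c_half == pytest.approx(150.0, abs=1e-6)
        assert fit.b_max == pytest.approx(0.9, abs=1e-6)

    def test_noisy_median_relative_error_under_10pct(self):
        errors = []
        for seed in range(100):
            s = simulate_emsa(150.0, 0.9, self.CONC, 0.03,
                              np.random.default_rng(seed))
            fit = fit_hill(s)
            if fit.success:
                errors.append(abs(fit.c_half - 150.0) / 150.0)
        assert len(errors) >= 95
        assert np.median(errors) < 0.10

    def test_too_few_points_rejected(self):
        s = BindingSeries([50.0, 150.0, 400.0], [1, 5, 9], [9, 5, 1])
        with pytest.raises(ValueError):
            fit_hill(s)


class TestGroupSummary:
    def test_small_sample(self):
        s = group_summary(GroupSample("a", [1.0, 2.0, 3.0]))
        assert s.median == 2.0 and s.n == 3

    def test_single_value(self):
        s = group_summary(GroupSample("a", [7.0]))
        assert s.median == 7.0
        assert s.q3 - s.q1 == 0.0

    def test_matches_sorting_oracle(self, rng):
        for _ in range(200):
            vals = rng.normal(10, 3, rng.integers(2, 40))
            s = group_summary(GroupSample("x", vals))
            srt = np.sort(vals)
            assert s.median == pytest.approx(np.quantile(srt, 0.5))
            assert s.q1 == pytest.approx(np.quantile(srt, 0.25))
            assert s.q3 == pytest.approx(np.quantile(srt, 0.75))


class TestHolm:
    def test_hand_computed_pair(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_ties(self):
        out = holm_adjust([0.02, 0.02, 0.02])
        assert out == pytest.approx([0.06, 0.06, 0.06])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 12))
            ours = holm_adjust(p)
            _, theirs, _, _ = multipletests(p, method="holm")
            assert np.allclose(ours, theirs)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_properties(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestCompareGroups:
    def test_identical_groups_degenerate(self):
        samples = [GroupSample("a", [5.0] * 10), GroupSample("b", [5.0] * 10)]
        res = compare_groups(samples)
        assert res.kruskal_H == 0.0 and res.kruskal_p == 1.0

    def test_two_group_t_squared_equals_F(self, rng):
        # classical identity (pooled-variance t on two groups)
        a, b = rng.normal(10, 2, 20), rng.normal(12, 2, 20)
        F, _ = sps.f_oneway(a, b)
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert t**2 == pytest.approx(F, rel=1e-10)

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(2026)
        hits = 0
        reps = 1000
        for _ in range(reps):
            groups = [GroupSample(str(i), rng.normal(10, 2, 12))
                      for i in range(3)]
            if compare_groups(groups).anova_p < 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) <= 0.02

    def test_pairwise_gated_by_anova(self, rng):
        far = [GroupSample("a", rng.normal(0, 1, 30)),
               GroupSample("b", rng.normal(5, 1, 30))]
        res = compare_groups(far)
        assert res.posthoc_significant
        assert set(res.pairwise.columns) >= {"group_a", "group_b", "p",
                                             "p_holm"}


class TestRecombination:
    def test_plain_ratio(self):
        res = recombination_frequency([10], [10**6])
        assert res.frequency == pytest.approx(1e-5)
        assert not res.is_limit_of_detection

    def test_limit_of_detection_rule(self):
        # zero recombinants in 3 reps of 1e6 -> 1 / (3e6), flagged, no SD
        res = recombination_frequency([0, 0, 0], [10**6] * 3)
        assert res.is_limit_of_detection
        assert res.frequency == pytest.approx(1.0 / 3e6)
        assert res.sd is None

    def test_single_replicate_sd_undefined(self):
        res = recombination_frequency([5], [10**6])
        assert res.frequency == pytest.approx(5e-6)
        assert res.sd is None

    def test_mean_of_replicates(self):
        res = recombination_frequency([10, 20, 30], [10**6] * 3)
        assert res.frequency == pytest.approx(2e-5)
        assert res.sd is not None


class TestCorrelation:
    def test_perfect_exponential_on_log_scale(self):
        forces = np.array([6.0, 8.0, 10.0, 12.7])
        eff = 10.0 ** (0.5 * forces - 4)
        res = stability_efficiency_correlation(forces, eff)
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_efficiency_undefined(self):
        res = stability_efficiency_correlation([6.0, 8.0, 10.0],
                                               [1.0, 1.0, 1.0])
        assert np.isnan(res.pearson_r)
        assert "undefined" in res.note

    def test_random_pairs_mean_r_near_zero(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(1000):
            f = rng.normal(10, 2, 6)
            e = 10.0 ** rng.normal(-4, 1, 6)
            rs.append(stability_efficiency_correlation(f, e).pearson_r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) <= 3 * se

    def test_lod_conditions_excluded_by_default(self):
        forces = [6.0, 8.0, 10.0, 12.0]
        eff = [1e-7, 1e-5, 1e-4, 1e-3]
        res = stability_efficiency_correlation(forces, eff,
                                               lod_flags=[True, False, False,
                                                          False])
        assert res.n == 3 and res.n_lod_excluded == 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            stability_efficiency_correlation([6.0, 8.0], [1e-5, 1e-4])
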