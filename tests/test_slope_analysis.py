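import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from emgforce import (
    LevelSeries,
    RegionSpec,
    SlopeMap,
    rms,
    fit_loglog,
    slope_map,
    region_mean,
    wilcoxon_signed_rank,
    effect_size_r,
    anova_bonferroni,
    ks_normality,
)


class TestRms:
    def test_constant_signal(self):
        assert rms(np.full(100, -3.0)) == pytest.approx(3.0)

    def test_sine_over_whole_periods(self):
        t = np.arange(1000) / 1000.0
        assert rms(2.5 * np.sin(2 * np.pi * 5 * t)) == pytest.approx(2.5 / np.sqrt(2), rel=1e-6)

    def test_hand_computed_pair(self):
        assert rms([3.0, -4.0]) == pytest.approx(np.sqrt(12.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms([])


class TestFitLoglog:
    def test_identity_power_law(self):
        x = np.linspace(1, 10, 10)
        fit = fit_loglog(LevelSeries(force=x, amplitude=x))
        assert fit.b == pytest.approx(1.0, abs=1e-12)
        assert fit.ln_a == pytest.approx(0.0, abs=1e-12)

    def test_exact_power_law_with_prefactor(self):
        x = np.linspace(0.5, 8, 12)
        fit = fit_loglog(LevelSeries(force=x, amplitude=2.0 * x**1.5))
        assert fit.b == pytest.approx(1.5, abs=1e-12)
        assert fit.ln_a == pytest.approx(np.log(2.0), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        b=st.floats(0.5, 2.0),
        a=st.floats(0.1, 10.0),
    )
    def test_recovers_any_noiseless_power_law(self, b, a):
        x = np.linspace(1.0, 5.0, 8)
        fit = fit_loglog(LevelSeries(force=x, amplitude=a * x**b))
        assert fit.b == pytest.approx(b, abs=1e-9)
        assert fit.ln_a == pytest.approx(np.log(a), abs=1e-9)

    def test_noisy_power_law_matches_normal_equation_oracle(self, rng):
        x = np.linspace(1, 10, 30)
        y = 1.7 * x**1.2 * np.exp(rng.normal(0, 0.1, 30))
        fit = fit_loglog(LevelSeries(force=x, amplitude=y))
        # oracle: explicit normal-equation solve on the log pairs
        lx, ly = np.log(x), np.log(y)
        A = np.column_stack([lx, np.ones_like(lx)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ ly)
        assert fit.b == pytest.approx(slope, abs=1e-10)
        assert fit.ln_a == pytest.approx(intercept, abs=1e-10)

    def test_scale_invariance_of_slope(self, rng):
        x = np.linspace(2, 20, 10)
        y = 0.3 * x**1.4 * np.exp(rng.normal(0, 0.05, 10))
        raw = fit_loglog(LevelSeries(force=x, amplitude=y))
        norm = fit_loglog(LevelSeries(force=x, amplitude=y).normalized())
        # renormalization shifts only ln_a; b agrees to floating precision
        assert norm.b == pytest.approx(raw.b, abs=1e-12)
        assert norm.ln_a != raw.ln_a

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_loglog(LevelSeries(force=np.ones(5), amplitude=np.ones(5)))
        with pytest.raises(ValueError):
            LevelSeries(force=np.array([1.0, -2.0, 3.0]), amplitude=np.ones(3))


class TestSlopeMap:
    def test_identical_channels_give_constant_map(self):
        x = np.linspace(1, 4, 5)
        amp = np.tile((2 * x**1.3)[:, None], (1, 6))
        smap = slope_map(LevelSeries(force=x, amplitude=amp), (2, 3))
        np.testing.assert_allclose(smap.values, 1.3)

    def test_permutation_equivariance(self, rng):
        x = np.linspace(1, 4, 6)
        amp = np.exp(rng.normal(0, 0.2, (6, 12))) * x[:, None] ** rng.uniform(0.5, 2, 12)
        base = slope_map(LevelSeries(force=x, amplitude=amp), (3, 4))
        perm = rng.permutation(12)
        cells = np.column_stack([np.repeat(np.arange(3), 4), np.tile(np.arange(4), 3)])
        permuted = slope_map(
            LevelSeries(force=x, amplitude=amp[:, perm]), (3, 4), channel_to_cell=cells[perm]
        )
        np.testing.assert_allclose(permuted.values, base.values)

    def test_failed_channels_marked_missing(self):
        x = np.linspace(1, 4, 5)
        amp = np.tile(x[:, None], (1, 4)).copy()
        amp[2, 1] = 0.0  # non-positive amplitude: channel cannot be log-fitted
        smap = slope_map(LevelSeries(force=x, amplitude=amp), (2, 2))
        assert np.isnan(smap.values[0, 1])
        assert np.isfinite(smap.values).sum() == 3

    def test_mean_channel_fit_equals_fit_of_mean_series(self, rng):
        x = np.linspace(1, 4, 6)
        amp = np.exp(rng.normal(0, 0.1, (6, 8))) * x[:, None] ** 1.2
        whole = fit_loglog(LevelSeries(force=x, amplitude=amp.mean(axis=1)))
        direct = fit_loglog(LevelSeries(force=x, amplitude=amp.mean(axis=1)[:, None]))
        assert whole.b == direct.b


class TestRegionMean:
    def test_constant_map(self):
        smap = SlopeMap(values=np.full((13, 10), 1.2))
        assert region_mean(smap, RegionSpec(), "proximal") == pytest.approx(1.2)

    def test_checkerboard_hand_computed(self):
        values = np.indices((13, 10)).sum(axis=0) % 2  # 0/1 checkerboard
        smap = SlopeMap(values=values.astype(float))
        # proximal = rows 3-4 (1-based) over all 10 columns: exactly half ones
        assert region_mean(smap, RegionSpec(), "proximal") == pytest.approx(0.5)

    def test_single_channel_region(self):
        values = np.arange(130, dtype=float).reshape(13, 10)
        spec = RegionSpec(proximal_rows=(2,), lateral_cols=(3,))
        r, c = spec.region_indices("proximal", (13, 10))
        assert region_mean(SlopeMap(values=values), spec, "proximal") == pytest.approx(
            values[1].mean()
        )

    def test_out_of_grid_region_rejected(self):
        smap = SlopeMap(values=np.zeros((13, 5)))
        with pytest.raises(IndexError):
            region_mean(smap, RegionSpec(medial_cols=(9, 10)), "medial")


class TestWilcoxon:
    def test_exact_p_matches_exhaustive_enumeration(self):
        a = np.array([1.2, 0.8, 1.5, 1.1, 0.9, 1.3])
        b = np.array([1.0, 0.9, 1.1, 0.7, 1.0, 0.9])
        _, p, _ = wilcoxon_signed_rank(a, b, method="exact")
        # oracle: enumerate all 2^6 sign assignments of the ranks
        d = a - b
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = []
        for mask in range(2**6):
            signs = [(mask >> i) & 1 for i in range(6)]
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.array(ws)
        lo = np.mean(ws <= w_obs)
        hi = np.mean(ws >= w_obs)
        assert p == pytest.approx(min(1.0, 2 * min(lo, hi)), abs=1e-12)

    def test_z_antisymmetric_under_swap(self, rng):
        a = rng.normal(1.0, 0.2, 9)
        b = rng.normal(0.9, 0.2, 9)
        z_ab, _, r_ab = wilcoxon_signed_rank(a, b, method="approx")
        z_ba, _, r_ba = wilcoxon_signed_rank(b, a, method="approx")
        assert z_ab == pytest.approx(-z_ba)
        assert r_ab == pytest.approx(r_ba)

    def test_matches_scipy_normal_approximation(self, rng):
        a = rng.normal(1.0, 0.3, 15)
        b = rng.normal(0.8, 0.3, 15)
        z, p, _ = wilcoxon_signed_rank(a, b, method="approx")
        ref = sps.wilcoxon(a, b, correction=True, method="approx", zero_method="wilcox")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert abs(z) == pytest.approx(abs(ref.zstatistic), rel=1e-9)

    def test_effect_size_from_printed_statistic(self):
        assert effect_size_r(2.67, 9) == pytest.approx(0.89, abs=0.005)

    def test_identical_pairs_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))


class TestAnovaBonferroni:
    def test_identical_groups_no_effect(self):
        g = [np.full(5, 2.0)] * 3
        p, pairwise = anova_bonferroni(g)
        assert p == 1.0
        assert all(v == 1.0 for v in pairwise.values())

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        f, _ = sps.f_oneway(a, b)
        t, _ = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        p, pairwise = anova_bonferroni([a, b])
        assert pairwise[(0, 1)] == pytest.approx(min(1.0, sps.ttest_ind(a, b).pvalue), rel=1e-12)

    def test_fixed_table_matches_hand_computed_sums_of_squares(self):
        groups = [
            np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            np.array([2.0, 3.0, 4.0, 5.0, 6.0]),
            np.array([5.0, 6.0, 7.0, 8.0, 9.0]),
        ]
        # hand computation: group means 3, 4, 7; grand mean 14/3
        # SS_between = 5*((3-14/3)^2 + (4-14/3)^2 + (7-14/3)^2) = 5*(25/9+4/9+49/9) = 130/3
        # SS_within = 3 * 10 = 30; F = (130/3/2) / (30/12) = (65/3)/2.5 = 26/3
        p, _ = anova_bonferroni(groups)
        f, p_ref = sps.f_oneway(*groups)
        assert f == pytest.approx(26.0 / 3.0, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_bonferroni_caps_at_one(self, rng):
        groups = [rng.normal(0, 1, 6) for _ in range(3)]
        _, pairwise = anova_bonferroni(groups)
        assert all(v <= 1.0 for v in pairwise.values())


class TestKsNormality:
    def test_gaussian_sample_accepted(self, rng):
        assert ks_normality(rng.normal(3.0, 1.0, 300)) > 0.05

    def test_exponential_sample_rejected(self, rng):
        assert ks_normality(rng.exponential(1.0, 100)) < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(20))
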