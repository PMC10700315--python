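import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dungbef import effect_meta as em
from dungbef.synthetic_data import simulate_effect_sizes


def _effects(g, var_g, lat=None, lon=None):
    df = pd.DataFrame({"g": g, "var_g": var_g})
    if lat is not None:
        df["latitude"], df["longitude"] = lat, lon
    return df


class TestHedgesG:
    def test_hand_derived_example(self):
        """low={2,3,4}, high={1,2,3}: d=1, J=0.8, g=0.8."""
        es = em.hedges_g([2, 3, 4], [1, 2, 3])
        assert es.g == pytest.approx(0.8, abs=1e-15)
        # var = J^2 [ (n1+n2)/(n1 n2) + d^2/(2(n1+n2-2)) ]
        assert es.var_g == pytest.approx(0.64 * (6 / 9 + 1 / 8), abs=1e-15)

    def test_identical_groups_give_zero(self):
        assert em.hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).g == 0.0

    def test_antisymmetry_under_group_swap(self, rng):
        a, b = rng.normal(2, 1, 10), rng.normal(0, 1, 10)
        e1, e2 = em.hedges_g(a, b), em.hedges_g(b, a)
        assert e1.g == pytest.approx(-e2.g, abs=1e-12)
        assert e1.var_g == pytest.approx(e2.var_g, abs=1e-12)

    def test_shift_and_scale_invariance(self, rng):
        a, b = rng.normal(2, 1, 8), rng.normal(0, 1, 8)
        base = em.hedges_g(a, b).g
        assert em.hedges_g(a + 7, b + 7).g == pytest.approx(base, abs=1e-10)
        assert em.hedges_g(3 * a, 3 * b).g == pytest.approx(base, abs=1e-10)

    def test_zero_pooled_sd_with_unequal_means_is_degenerate(self):
        with pytest.raises(ValueError, match="pooled"):
            em.hedges_g([1.0, 1.0], [2.0, 2.0])


class TestSpatialCorrelation:
    @pytest.mark.parametrize("kind", ["exponential", "gaussian",
                                      "rational_quadratic", "spherical"])
    def test_self_correlation_is_one(self, kind):
        assert em.spatial_correlation(0.0, 100.0, kind) == pytest.approx(1.0)

    def test_closed_forms(self):
        assert em.spatial_correlation(100.0, 100.0, "exponential") == \
            pytest.approx(math.exp(-1))
        assert em.spatial_correlation(50.0, 100.0, "gaussian") == \
            pytest.approx(math.exp(-0.25))
        assert em.spatial_correlation(100.0, 100.0, "rational_quadratic") == \
            pytest.approx(0.5)

    def test_spherical_compact_support(self):
        assert em.spatial_correlation(100.0, 100.0, "spherical") == 0.0
        assert em.spatial_correlation(250.0, 100.0, "spherical") == 0.0
        assert em.spatial_correlation(50.0, 100.0, "spherical") == \
            pytest.approx(1 - 1.5 * 0.5 + 0.5 * 0.125)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            em.spatial_correlation(10.0, 0.0, "exponential")


class TestGreatCircle:
    def test_identical_points(self):
        assert em.great_circle_distance(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_symmetry(self):
        d1 = em.great_circle_distance(10.0, 20.0, -35.0, 140.0)
        d2 = em.great_circle_distance(-35.0, 140.0, 10.0, 20.0)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_quarter_circumference_on_equator(self):
        d = em.great_circle_distance(0.0, 0.0, 0.0, 90.0)
        assert d == pytest.approx(2 * math.pi * 6371.0 / 4, rel=1e-9)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            em.great_circle_distance(95.0, 0.0, 0.0, 0.0)


class TestRandomEffectsFit:
    def test_equal_variance_limit_gives_arithmetic_mean(self, rng):
        g = rng.normal(0.4, 1.0, 12)
        fit = em.random_effects_fit(_effects(g, np.full(12, 0.3)))
        assert fit.mu == pytest.approx(float(np.mean(g)), abs=1e-10)

    def test_tau2_matches_grid_search_oracle(self):
        """REML point estimate agrees with a brute-force profile of the
        restricted likelihood over tau^2 on a 5-effect fixture."""
        g = np.array([0.2, 1.4, -0.6, 2.1, 0.9])
        v = np.array([0.15, 0.3, 0.2, 0.45, 0.25])
        fit = em.random_effects_fit(_effects(g, v))

        def rll(tau2):
            V = v + tau2
            w = 1 / V
            mu = (w * g).sum() / w.sum()
            return -0.5 * (np.log(V).sum() + math.log(w.sum())
                           + (w * (g - mu) ** 2).sum())

        grid = np.linspace(0.0, 10.0, 100001)
        best = grid[np.argmax([rll(t) for t in grid])]
        assert fit.tau2 == pytest.approx(best, abs=1e-4)

    def test_rho_to_zero_recovers_independent_fit(self, rng):
        eff, _ = simulate_effect_sizes(n=15, tau=1.0, seed=3)
        base = em.random_effects_fit(eff, structure="none")
        for kind in ("exponential", "gaussian", "spherical"):
            tiny = em.random_effects_fit(eff, structure=kind, rho=1e-6)
            assert tiny.mu == pytest.approx(base.mu, abs=1e-6)
            assert tiny.tau2 == pytest.approx(base.tau2, rel=1e-3, abs=1e-6)

    def test_parameter_recovery_at_large_n(self):
        """200 simulated effects with mu=0.5, T^2=1 recover the truth."""
        eff, _ = simulate_effect_sizes(n=200, gamma0=0.5, tau=1.0, seed=11)
        fit = em.random_effects_fit(eff)
        assert fit.mu == pytest.approx(0.5, abs=0.25)
        assert fit.tau2 == pytest.approx(1.0, abs=0.4)
        assert 0 <= fit.I2 < 1

    def test_aicc_and_intervals_are_finite(self, rng):
        eff, _ = simulate_effect_sizes(n=20, tau=1.0, seed=5)
        fit = em.random_effects_fit(eff)
        assert math.isfinite(fit.aicc)
        assert fit.ci_low < fit.mu < fit.ci_high
        assert fit.df == 19


class TestHeterogeneity:
    def test_no_dispersion_gives_zero_Q(self):
        out = em.heterogeneity(_effects([0.7] * 6, [0.2] * 6))
        assert out["Q"] == pytest.approx(0.0, abs=1e-12)
        assert out["df"] == 5

    def test_Q_matches_brute_force_summation(self):
        g = np.array([0.1, 0.8, -0.4, 1.2])
        v = np.array([0.2, 0.3, 0.25, 0.4])
        w = 1 / v
        mu_fe = (w * g).sum() / w.sum()
        expected = (w * (g - mu_fe) ** 2).sum()
        out = em.heterogeneity(_effects(g, v))
        assert out["Q"] == pytest.approx(expected, rel=1e-12)
        assert out["p"] == pytest.approx(stats.chi2.sf(expected, 3), rel=1e-12)

    def test_homogeneous_Q_behaves_like_chi_square(self, rng):
        """Under T^2 = 0 Cochran's Q has mean about n - 1."""
        n, reps = 10, 300
        qs = []
        for _ in range(reps):
            v = rng.uniform(0.1, 0.5, n)
            g = rng.normal(0.3, np.sqrt(v))
            qs.append(em.heterogeneity(_effects(g, v))["Q"])
        assert np.mean(qs) == pytest.approx(n - 1, abs=0.8)


class TestMetaRegression:
    def test_orthogonal_moderators_have_unit_vif(self, rng):
        n = 24
        x1 = np.tile([-1.0, 1.0], n // 2)
        x2 = np.repeat([-1.0, 1.0], n // 2)
        eff, _ = simulate_effect_sizes(n=n, tau=1.0, seed=8)
        fit = em.meta_regression(eff, pd.DataFrame({"x1": x1, "x2": x2}))
        assert np.allclose(fit.table["vif"].iloc[1:], 1.0, atol=1e-10)

    def test_degrees_of_freedom_bookkeeping(self):
        """38 sites and 3 moderators give omnibus df (3, 34), t df 34."""
        eff, x = simulate_effect_sizes(n=38, tau=1.0, seed=9)
        rng2 = np.random.default_rng(1)
        mods = pd.DataFrame({"a": x, "b": rng2.normal(size=38),
                             "c": rng2.normal(size=38)})
        fit = em.meta_regression(eff, mods)
        assert fit.F_df == (3, 34)
        assert (fit.table["df"] == 34).all()
        assert 0.0 <= fit.pseudo_R2 <= 1.0

    def test_collinear_moderators_rejected(self, rng):
        eff, x = simulate_effect_sizes(n=20, tau=1.0, seed=10)
        mods = pd.DataFrame({"a": x, "b": 2 * x.to_numpy() + 1e-9})
        with pytest.raises(ValueError, match="PCA"):
            em.meta_regression(eff, mods)

    def test_built_in_slope_recovered(self):
        eff, x = simulate_effect_sizes(n=150, gamma1=0.6, tau=0.8, seed=12)
        fit = em.meta_regression(eff, pd.DataFrame({"x": x.to_numpy()}))
        row = fit.table[fit.table["term"] == "x"].iloc[0]
        assert row["estimate"] == pytest.approx(0.6, abs=3 * row["se"])
        assert row["p"] < 0.01


class TestStructureSelection:
    def test_single_candidate_is_returned(self, rng):
        eff, _ = simulate_effect_sizes(n=12, tau=1.0, seed=13)
        best, table = em.select_structure(eff, candidates=("none",))
        assert best.structure == "none"
        assert len(table) == 1

    def test_comparison_table_has_one_row_per_converged_candidate(self):
        eff, _ = simulate_effect_sizes(n=15, tau=1.0, seed=14)
        best, table = em.select_structure(eff)
        assert set(table["structure"]) <= set(em.STRUCTURES)
        assert len(table) == len(set(table["structure"]))
        assert table["aicc"].is_monotonic_increasing

    def test_exponential_data_select_exponential_above_chance(self):
        """Effects simulated with strong exponential spatial correlation
        make AICc pick the exponential structure well above the 1-in-5
        chance rate across seeds."""
        wins = 0
        for seed in range(8):
            eff, _ = simulate_effect_sizes(n=120, tau=2.5, seed=50_000 + seed,
                                           structure="exponential", rho=100.0,
                                           coords_scale_deg=5.0)
            best, _ = em.select_structure(eff)
            wins += best.structure == "exponential"
        assert wins >= 3   # chance would average 1.6 of 8


class TestPairedWilcoxon:
    def test_no_signal_gives_p_one(self):
        with pytest.warns(UserWarning):
            stat, p = em.paired_wilcoxon([1.0, 2, 3, 4, 5, 6], [1.0, 2, 3, 4, 5, 6])
        assert p == 1.0

    def test_two_tailed_symmetry_under_swap(self, rng):
        a, b = rng.normal(1, 1, 12), rng.normal(0, 1, 12)
        _, p1 = em.paired_wilcoxon(a, b)
        _, p2 = em.paired_wilcoxon(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_exact_p_matches_sign_flip_enumeration_at_n6(self):
        """The exact two-sided p equals enumeration of all 2^6 sign
        assignments of the ranked absolute differences."""
        low = np.array([5.0, 3.0, 9.0, 7.0, 12.0, 4.0])
        high = np.array([2.0, 4.0, 5.0, 5.0, 5.0, 9.0])   # tie-free |differences|
        d = low - high
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        dist = np.array([sum(r for s, r in zip(signs, ranks) if s)
                         for signs in itertools.product([0, 1], repeat=6)])
        p_exact = min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))
        stat, p = em.paired_wilcoxon(low, high)
        assert p == pytest.approx(p_exact, rel=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            em.paired_wilcoxon([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
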