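"""Welch ANOVA, Games-Howell, Hedges g, effect bins, chi-square, screening."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from gwinet import (
    DegenerateGroupError,
    chi_square_categorical,
    generate_cohort,
    hedges_g_corrected,
    hedges_g_from_summary,
    interpret_effect,
    screen_measures,
    welch_anova,
    welch_anova_many,
)
from gwinet.groupstats import games_howell

THREE_GROUPS = ([1, 2, 3, 4], [2, 3, 4, 5], [10, 11, 12, 13])


def studentized_range_sf_oracle(q, k, df):
    """Tail probability of the studentized range by direct double integration.

    P(Q > q) = 1 - integral over the scale s of the chi-distribution density
    (df) times the range probability k * int phi(z) [Phi(z) - Phi(z - q s)]^(k-1) dz.
    Independent of scipy.stats.studentized_range.
    """

    def inner(s):
        def f(z):
            return stats.norm.pdf(z) * (
                stats.norm.cdf(z) - stats.norm.cdf(z - q * s)
            ) ** (k - 1)

        val, _ = integrate.quad(f, -8.0, 8.0, epsabs=1e-10, limit=200)
        return k * val

    # density of s = sqrt(chi2_df / df)
    log_norm = (df / 2.0) * math.log(df / 2.0) - math.lgamma(df / 2.0)

    def outer(s):
        log_pdf = log_norm + (df - 1) * math.log(s) - df * s * s / 2.0 + math.log(2.0)
        return math.exp(log_pdf) * inner(s)

    cdf, _ = integrate.quad(outer, 1e-8, 10.0, epsabs=1e-9, limit=200)
    return 1.0 - cdf


class TestWelchAnova:
    def test_identical_groups_give_zero_F(self):
        res = welch_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """Hand evaluation: equal variances 5/3, means 2.5/3.5/11.5 ->
        F* = 58.4 / (10/9) = 52.56 with df = (2, 6)."""
        res = welch_anova(THREE_GROUPS)
        assert res.F == pytest.approx(52.56, abs=0.005)
        assert res.df1 == 2
        assert res.df2 == pytest.approx(6.0, abs=1e-9)

    def test_k2_equals_squared_welch_t(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 2, 12)
        res = welch_anova([x, y])
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert res.F == pytest.approx(t**2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_cross_check_against_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        vals = [rng.normal(m, s, n) for m, s, n in
                ((0, 1, 15), (0.4, 2, 25), (1, 0.5, 10))]
        res = welch_anova(vals)
        df = pd.DataFrame(
            {
                "y": np.concatenate(vals),
                "grp": np.repeat(["a", "b", "c"], [15, 25, 10]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="grp").iloc[0]
        assert res.F == pytest.approx(ref["F"], rel=1e-9)
        assert res.p == pytest.approx(ref["p_unc"], rel=1e-9)
        assert res.df2 == pytest.approx(ref["ddof2"], rel=1e-9)

    def test_zero_variance_group_flagged(self):
        with pytest.raises(DegenerateGroupError):
            welch_anova([[1.0, 1.0, 1.0], [1, 2, 3]])

    def test_vectorized_matches_scalar(self, rng):
        groups = [rng.normal(size=(12, 5)), rng.normal(size=(8, 5)),
                  rng.normal(size=(20, 5))]
        F, p = welch_anova_many(groups)
        for j in range(5):
            res = welch_anova([g[:, j] for g in groups])
            assert F[j] == pytest.approx(res.F)
            assert p[j] == pytest.approx(res.p)


class TestGamesHowell:
    def test_identical_groups(self):
        res = games_howell([[1.0, 2, 3], [1.0, 2, 3]])
        assert res[0].mean_diff == 0.0
        assert res[0].p_gh == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        """Pair {1..4} vs {10..13}: t = 9/sqrt(2*5/12) = 9.859, df = 6."""
        res = games_howell(THREE_GROUPS)
        pair = next(r for r in res if r.pair == ("group0", "group2"))
        assert abs(pair.t) == pytest.approx(9.8590, abs=1e-3)
        assert pair.df_welch == pytest.approx(6.0, abs=1e-9)
        assert pair.q_stat == pytest.approx(abs(pair.t) * math.sqrt(2))
        assert pair.p_gh < 0.001

    def test_p_matches_numeric_integration_oracle(self):
        res = games_howell(THREE_GROUPS)
        pair = next(r for r in res if r.pair == ("group0", "group2"))
        oracle = studentized_range_sf_oracle(pair.q_stat, k=3, df=pair.df_welch)
        assert pair.p_gh == pytest.approx(oracle, abs=1e-6)

    def test_two_group_case_matches_welch_t_oracle(self, rng):
        """k=2: studentized range at |t|*sqrt(2) reproduces the Welch t p."""
        x, y = rng.normal(0, 1, 14), rng.normal(0.8, 2, 9)
        res = games_howell([x, y])[0]
        _, p_welch = stats.ttest_ind(x, y, equal_var=False)
        oracle = studentized_range_sf_oracle(res.q_stat, k=2, df=res.df_welch)
        assert res.p_gh == pytest.approx(p_welch, abs=1e-6)
        assert res.p_gh == pytest.approx(oracle, abs=1e-6)

    def test_cross_check_against_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        vals = [rng.normal(m, s, n) for m, s, n in
                ((0, 1, 15), (0.6, 2, 25), (1, 0.5, 10))]
        ours = games_howell(vals, labels=["a", "b", "c"])
        df = pd.DataFrame(
            {
                "y": np.concatenate(vals),
                "grp": np.repeat(["a", "b", "c"], [15, 25, 10]),
            }
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="grp")
        for r in ours:
            row = ref[(ref["A"] == r.pair[0]) & (ref["B"] == r.pair[1])].iloc[0]
            assert r.p_gh == pytest.approx(row["pval"], abs=1e-6)
            assert r.df_welch == pytest.approx(row["df"], rel=1e-9)

    def test_p_nonincreasing_in_t(self):
        """Holding k and df fixed, larger |t| never raises the adjusted p."""
        ts = np.linspace(0.1, 6.0, 25)
        ps = [
            float(stats.studentized_range.sf(t * math.sqrt(2), 3, 20.0))
            for t in ts
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestHedgesG:
    def test_equal_means_zero(self):
        assert hedges_g_corrected([1, 2, 3], [2, 1, 3]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        """{1..5} vs {3..7}: d = -2/sqrt(2.5) = -1.2649, J = 1 - 3/31."""
        g = hedges_g_corrected([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        assert g == pytest.approx(-1.1425, abs=1e-4)

    def test_summary_mode_reproduces_reported_medium_bin(self):
        """IL-15 at rest from group summaries: medium effect (0.50-0.80)."""
        g = hedges_g_from_summary(
            0.24, 0.03 * math.sqrt(44), 44, 0.15, 0.02 * math.sqrt(29), 29
        )
        assert interpret_effect(g) == "medium"

    def test_sign_antisymmetry_and_scale_invariance(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(1, 2, 17)
        g1 = hedges_g_corrected(x, y)
        assert hedges_g_corrected(y, x) == pytest.approx(-g1)
        assert hedges_g_corrected(3 * x + 5, 3 * y + 5) == pytest.approx(g1)

    def test_zero_pooled_sd_flagged(self):
        with pytest.raises(DegenerateGroupError):
            hedges_g_corrected([2.0, 2.0], [2.0, 2.0])


@pytest.mark.parametrize(
    "g, expected",
    [
        (0.0, "negligible"),
        (0.58, "medium"),
        (-1.04, "large"),
        (0.005, "negligible"),
        (0.15, "very small"),
        (0.35, "small"),
        (1.5, "very large"),
        (-2.5, "huge"),
        (0.5, "medium"),  # left edges inclusive
        (0.8, "large"),
    ],
)
def test_effect_bins(g, expected):
    assert interpret_effect(g) == expected


class TestChiSquare:
    def test_independent_table(self):
        chi2, df, p = chi_square_categorical([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """[[20,10],[10,20]]: expected 15 everywhere, chi2 = 4*25/15."""
        chi2, df, p = chi_square_categorical([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(6.6667, abs=1e-3)
        assert df == 1

    def test_identical_row_profiles(self):
        chi2, _, _ = chi_square_categorical([[5, 10], [10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_categorical([[0, 0], [5, 5]])


class TestScreen:
    def test_omnibus_gate(self, study_config):
        """Measures failing the omnibus screen produce zero pairwise rows."""
        cohort = generate_cohort(study_config)
        res = screen_measures(cohort, "T0")
        gated_out = set(res.omnibus.loc[res.omnibus["p"] >= 0.05, "measure"])
        if len(res.pairwise):
            assert gated_out.isdisjoint(set(res.pairwise["measure"]))

    def test_absent_measure_skipped_with_log(self, study_config):
        cohort = generate_cohort(study_config)
        res = screen_measures(cohort, "T0", measures=["IL-15", "nonexistent"])
        assert any(s["measure"] == "nonexistent" for s in res.skipped)
        assert set(res.omnibus["measure"]) == {"IL-15"}

    def test_groups_dropped_pairwise_per_measure(self, study_config):
        """TNF-RI exists only on the 18-plex, so its per-group n is smaller."""
        cohort = generate_cohort(study_config)
        res = screen_measures(cohort, "T0", measures=["TNF-RI", "RDW"])
        row_tnfr = res.omnibus.set_index("measure").loc["TNF-RI"]
        row_rdw = res.omnibus.set_index("measure").loc["RDW"]
        assert row_tnfr["n_HC"] < row_rdw["n_HC"]
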