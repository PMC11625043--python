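"""Inferential battery: hand examples, published summaries, independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from hemilat.errors import CollinearityError, DegenerateSignalError
from hemilat.group_stats import (
    GroupSummary,
    anova_from_summary,
    chi_square_independence,
    fdr_bh,
    games_howell,
    jonckheere_terpstra,
    levene,
    one_sample_t,
    oneway_anova,
    partial_correlation,
    t_from_summary,
    two_sample_t,
)


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        assert one_sample_t([-2.0, -1.0, 1.0, 2.0]).statistic == pytest.approx(0.0)

    def test_hand_computed(self):
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-9)  # 3.4641
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.effect == pytest.approx(2.0)
        assert res.df == (2.0,)

    def test_too_small_or_constant_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])
        with pytest.raises(DegenerateSignalError):
            one_sample_t([1.0, 1.0, 1.0])


class TestTwoSampleT:
    def test_education_summaries(self):
        """Pooled t from the published education summaries (OM vs ONM)."""
        res = t_from_summary(GroupSummary(13.15, 3.06, 23), GroupSummary(9.89, 2.80, 23))
        assert res.statistic == pytest.approx(3.769, abs=5e-4)
        assert res.df == (44.0,)
        assert res.effect == pytest.approx(1.112, abs=1e-3)

    def test_hearing_summaries(self):
        res = t_from_summary(GroupSummary(12.33, 5.42, 23), GroupSummary(12.57, 4.01, 23))
        assert abs(res.statistic) == pytest.approx(0.1707, abs=1e-3)

    def test_identical_summaries_zero(self):
        res = t_from_summary(GroupSummary(5.0, 1.0, 10), GroupSummary(5.0, 1.0, 10))
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_raw_equals_summary(self, rng):
        a, b = rng.standard_normal(15) + 0.5, rng.standard_normal(12)
        raw = two_sample_t(a, b, "welch")
        summ = t_from_summary(GroupSummary.of(a), GroupSummary.of(b), "welch")
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert raw.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert raw.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        res = levene([g, g, g])
        assert res.statistic == pytest.approx(0.0)

    def test_detects_fivefold_sd_ratio(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            res = levene([r.normal(0, 1, 30), r.normal(0, 5, 30)])
            hits += res.p < 0.05
        assert hits >= 38  # >= 95% power at this separation

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            levene([np.arange(5.0)])


class TestAnova:
    def test_equal_means_zero_f(self):
        g = [np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([1.0, 2.0])]
        assert oneway_anova(g, force="classic").statistic == pytest.approx(0.0)

    def test_hand_anova(self):
        # SSB = 2[(1.5-3.5)^2 + 0 + (5.5-3.5)^2] = 16, SSW = 3 * 0.5 = 1.5
        res = oneway_anova([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], force="classic")
        assert res.statistic == pytest.approx((16.0 / 2) / (1.5 / 3))
        assert res.df == (2.0, 3.0)
        ref = stats.f_oneway([1.0, 2.0], [3.0, 4.0], [5.0, 6.0])
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_sis_welch_from_published_summaries(self):
        summ = [GroupSummary(-5.43, 1.00, 24), GroupSummary(-4.97, 1.51, 23), GroupSummary(-0.31, 3.09, 23)]
        res = anova_from_summary(summ, "welch")
        assert res.statistic == pytest.approx(28.217, rel=5e-3)
        assert res.df[1] == pytest.approx(38.920, rel=5e-3)
        assert res.effect == pytest.approx(0.568, abs=2e-3)

    def test_digit_span_classic_from_published_summaries(self):
        summ = [GroupSummary(16.71, 2.71, 24), GroupSummary(15.09, 2.27, 23), GroupSummary(11.57, 2.06, 23)]
        res = anova_from_summary(summ, "classic")
        assert res.statistic == pytest.approx(28.749, rel=2e-3)
        assert res.df == (2.0, 67.0)
        assert res.effect == pytest.approx(0.462, abs=2e-3)

    def test_raw_equals_summary_oracle(self, rng):
        """oneway_anova(raw) == anova_from_summary(exact summaries) for both kinds."""
        for _ in range(10):
            groups = [rng.standard_normal(rng.integers(5, 20)) + rng.normal() for _ in range(3)]
            summ = [GroupSummary.of(g) for g in groups]
            for kind in ("classic", "welch"):
                raw = oneway_anova(groups, force=kind)
                s = anova_from_summary(summ, kind)
                assert raw.statistic == pytest.approx(s.statistic, abs=1e-10)
                assert raw.df[1] == pytest.approx(s.df[1], abs=1e-10)

    def test_welch_matches_pingouin(self, rng):
        groups = [rng.standard_normal(12) * s + m for s, m in ((1, 0), (2, 0.5), (0.5, 1.0))]
        res = oneway_anova(groups, force="welch")
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(list("abc"), [len(g) for g in groups])}
        )
        ref = pg.welch_anova(data=df, dv="y", between="g").iloc[0]
        assert res.statistic == pytest.approx(ref["F"], abs=1e-8)
        assert res.df[1] == pytest.approx(ref["ddof2"], abs=1e-6)
        assert res.p == pytest.approx(ref["p_unc"], abs=1e-8)

    def test_auto_gate_selects_welch_under_heteroscedasticity(self, rng):
        hetero = [rng.standard_normal(30), rng.standard_normal(30) * 6, rng.standard_normal(30)]
        assert oneway_anova(hetero, force="auto").method == "welch_f"
        homo = [rng.standard_normal(30) + m for m in (0, 0.1, 0.2)]
        assert oneway_anova(homo, force="auto").method == "classic_f"


class TestChiSquare:
    def test_published_gender_table(self):
        res = chi_square_independence([[12, 12], [9, 14], [14, 9]])
        assert res.statistic == pytest.approx(2.174, abs=5e-4)
        assert res.df == (2.0,)

    def test_proportional_table_zero(self):
        assert chi_square_independence([[10, 20], [5, 10]]).statistic == pytest.approx(0.0)

    def test_2x2_brute_force(self):
        table = np.array([[3.0, 7.0], [7.0, 3.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        ref = ((table - expected) ** 2 / expected).sum()
        res = chi_square_independence(table)
        assert ref == pytest.approx(3.2)
        assert res.statistic == pytest.approx(ref, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [1, 2]])


class TestGamesHowell:
    def test_identical_groups(self):
        g = np.arange(10.0)
        res = games_howell([g, g + 0.0, g])
        assert all(r.statistic == pytest.approx(0.0) for r in res)
        assert all(r.p > 0.99 for r in res)

    def test_large_shift_always_significant(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            groups = [r.normal(0, 1, 20), r.normal(0, 1, 20), r.normal(5, 1, 20)]
            res = {tuple(x.extra["pair"]): x for x in games_howell(groups, ["a", "b", "c"])}
            assert res[("a", "c")].p < 0.001 and res[("b", "c")].p < 0.001

    def test_matches_pingouin_oracle(self):
        """Agreement with an independent Games-Howell implementation on random instances."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            sizes = r.integers(5, 25, size=3)
            groups = [r.normal(r.normal(), r.uniform(0.5, 3), n) for n in sizes]
            mine = {tuple(x.extra["pair"]): x for x in games_howell(groups, ["a", "b", "c"])}
            df = pd.DataFrame(
                {"y": np.concatenate(groups), "g": np.repeat(list("abc"), sizes)}
            )
            ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
            for _, row in ref.iterrows():
                got = mine[(row["A"], row["B"])]
                assert abs(got.statistic) == pytest.approx(abs(row["T"]), abs=1e-8)
                assert got.df[0] == pytest.approx(row["df"], abs=1e-8)
                assert got.p == pytest.approx(row["pval"], abs=1e-6)

    def test_relabeling_invariance(self, rng):
        groups = [rng.standard_normal(8), rng.standard_normal(9) + 1, rng.standard_normal(7) - 1]
        p1 = sorted(r.p for r in games_howell(groups))
        p2 = sorted(r.p for r in games_howell(groups[::-1]))
        np.testing.assert_allclose(p1, p2, atol=1e-12)


def _jt_brute_force(groups):
    """Enumerate all cross-group pairs; ties add 1/2."""
    j = 0.0
    for a, b in itertools.combinations(groups, 2):
        for x in a:
            for y in b:
                j += (y > x) + 0.5 * (y == x)
    return j


class TestJonckheereTerpstra:
    def test_textbook_example(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]], "increasing")
        assert res.extra["J"] == 12.0
        assert res.extra["mu"] == 6.0
        assert res.extra["var"] == pytest.approx(19 / 3)
        assert res.statistic == pytest.approx(2.384, abs=1e-3)

    def test_fully_tied_defined_as_zero(self):
        res = jonckheere_terpstra([[1, 1], [1, 1], [1, 1]], "increasing")
        assert res.statistic == 0.0

    def test_reversing_group_order_negates_z(self, rng):
        groups = [rng.standard_normal(8) + m for m in (0.0, 0.4, 0.9)]
        z_fwd = jonckheere_terpstra(groups, "increasing").statistic
        z_rev = jonckheere_terpstra(groups[::-1], "increasing").statistic
        assert z_fwd == pytest.approx(-z_rev, abs=1e-12)

    def test_decreasing_trend_yields_negative_z(self, rng):
        groups = [rng.standard_normal(20) + m for m in (1.0, 0.5, 0.0)]
        res = jonckheere_terpstra(groups, "decreasing")
        assert res.statistic < 0 and res.p < 0.1

    def test_j_matches_brute_force_enumeration(self, rng):
        for _ in range(50):
            groups = [
                rng.integers(0, 6, size=rng.integers(2, 7)).astype(float) for _ in range(3)
            ]
            res = jonckheere_terpstra(groups, "increasing")
            assert res.extra["J"] == pytest.approx(_jt_brute_force(groups), abs=1e-9)

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2], [3, 4]], "increasing")


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        res = partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_shared_covariate_removes_correlation(self, rng):
        c = rng.standard_normal(200)
        x = c + rng.standard_normal(200) * 0.05
        y = c + rng.standard_normal(200) * 0.05
        assert abs(stats.pearsonr(x, y).statistic) > 0.99
        assert abs(partial_correlation(x, y, c).statistic) < 0.2

    def test_hand_least_squares_instance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        c = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        # residualize by hand: regress x and y on [1, c]
        design = np.column_stack([np.ones(6), c])
        bx = np.linalg.solve(design.T @ design, design.T @ x)
        by = np.linalg.solve(design.T @ design, design.T @ y)
        rx, ry = x - design @ bx, y - design @ by
        ref = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        res = partial_correlation(x, y, c)
        assert res.statistic == pytest.approx(ref, abs=1e-10)
        assert res.df == (3.0,)

    def test_matches_pingouin_oracle(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            data = pd.DataFrame(r.standard_normal((25, 4)), columns=["x", "y", "c1", "c2"])
            res = partial_correlation(data["x"], data["y"], data[["c1", "c2"]].to_numpy())
            ref = pg.partial_corr(data=data, x="x", y="y", covar=["c1", "c2"])
            assert res.statistic == pytest.approx(ref["r"].iloc[0], abs=1e-8)
            assert res.p == pytest.approx(ref["p_val"].iloc[0], abs=1e-8)

    def test_orthogonal_covariate_barely_changes_r(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        base = partial_correlation(x, y).statistic
        c = rng.standard_normal(60)
        design = np.column_stack([np.ones(60), x, y])
        c_orth = c - design @ np.linalg.lstsq(design, c, rcond=None)[0]
        assert partial_correlation(x, y, c_orth).statistic == pytest.approx(base, abs=1e-10)

    def test_collinear_design_rejected(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        c = rng.standard_normal(20)
        with pytest.raises(CollinearityError):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))

    def test_insufficient_n_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_correlation(np.ones(4), np.ones(4), np.ones((4, 2)))


class TestFdrBH:
    def test_hand_bh(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert fdr_bh([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_step_up_brute_force(self, rng):
        p = rng.uniform(size=20)
        order = np.argsort(p)
        ranked = p[order]
        m = len(p)
        raw = ranked * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(raw[::-1])[::-1].clip(max=1.0)
        expected = np.empty(m)
        expected[order] = adj
        np.testing.assert_allclose(fdr_bh(p), expected, atol=1e-12)

    def test_monotone_and_order_preserving(self, rng):
        p = rng.uniform(size=15)
        adj = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestTypeIError:
    def test_anova_and_jt_calibrated_under_null(self):
        """Rejection rates at alpha=0.05 within 0.05 +/- 0.01 over 2000 null replicates."""
        rng = np.random.default_rng(777)
        n_rep = 2000
        anova_rej = jt_rej = 0
        for _ in range(n_rep):
            groups = [rng.standard_normal(24), rng.standard_normal(23), rng.standard_normal(23)]
            if oneway_anova(groups, force="auto").p < 0.05:
                anova_rej += 1
            if jonckheere_terpstra(groups, "decreasing").p < 0.05:
                jt_rej += 1
        assert abs(anova_rej / n_rep - 0.05) < 0.01
        assert abs(jt_rej / n_rep - 0.05) < 0.01
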