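import numpy as np
import pytest
from scipy import stats

from crosstrait.enrichment import (
    ContingencyTable,
    ZeroMarginError,
    binomial_lookup,
    chisq_yates,
    enrich,
    proportion_ci,
    qq_points,
    sensitivity_grid,
    stratify_counts,
)


def yates_oracle(a, b, c, d):
    """Textbook formula: sum over cells of (max(0,|O-E|-0.5))^2/E."""
    obs = np.array([[a, b], [c, d]], float)
    n = obs.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = obs[i].sum() * obs[:, j].sum() / n
            stat += max(0.0, abs(obs[i, j] - e) - 0.5) ** 2 / e
    return stat, stats.chi2.sf(stat, 1)


class TestStratify:
    def test_tail_counts_from_constructed_pvalues(self):
        # 717 discovery-tail SNPs of which 52 clear the lookup cutoff
        n = 5000
        disc = np.full(n, 0.5)
        look = np.full(n, 0.5)
        disc[:717] = 1e-4
        look[:52] = 0.01
        t = stratify_counts(disc, look)
        assert (t.a, t.b) == (52, 665)
        assert t.n == n

    def test_all_p_one_lands_in_last_cell(self):
        t = stratify_counts(np.ones(30), np.ones(30))
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 30)

    def test_manual_enumeration_on_20_snps(self):
        rng = np.random.default_rng(5)
        disc = rng.uniform(size=20)
        look = rng.uniform(size=20)
        t1, t2 = 0.3, 0.4
        t = stratify_counts(disc, look, t1, t2)
        expect = [
            sum(1 for x, y in zip(disc, look) if (x < t1) == r and (y < t2) == c)
            for r in (True, False) for c in (True, False)
        ]
        assert [t.a, t.b, t.c, t.d] == expect

    def test_strict_threshold_semantics(self):
        t = stratify_counts([1e-3], [0.05], 1e-3, 0.05)
        assert (t.a, t.d) == (0, 1)  # values at the threshold fall in ">="


class TestChisqYates:
    def test_proportional_table_scores_zero(self):
        stat, p = chisq_yates(ContingencyTable(10, 90, 100, 900))
        assert stat == 0.0
        assert p == 1.0

    def test_matches_textbook_oracle_on_large_table(self):
        t = ContingencyTable(52, 665, 8622, 163818)
        stat, p = chisq_yates(t)
        ostat, op = yates_oracle(52, 665, 8622, 163818)
        assert stat == pytest.approx(ostat, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_matches_scipy_when_correction_binds(self):
        # away from the clamp region our statistic equals scipy's Yates chi2
        for cells in [(52, 665, 8622, 163818), (30, 70, 50, 150), (5, 95, 20, 380)]:
            stat, p = chisq_yates(ContingencyTable(*cells))
            ref = stats.chi2_contingency(
                np.array(cells).reshape(2, 2), correction=True
            )
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetry_under_row_and_column_swap(self):
        t = ContingencyTable(7, 13, 29, 51)
        base = chisq_yates(t)
        assert chisq_yates(ContingencyTable(29, 51, 7, 13)) == base   # rows
        assert chisq_yates(ContingencyTable(13, 7, 51, 29)) == base   # columns

    def test_never_exceeds_uncorrected_pearson(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            cells = rng.integers(1, 200, size=4)
            t = ContingencyTable(*map(int, cells))
            stat, _ = chisq_yates(t)
            pearson = stats.chi2_contingency(t.as_array(), correction=False).statistic
            assert stat <= pearson + 1e-12

    def test_zero_margin_raises(self):
        with pytest.raises(ZeroMarginError):
            chisq_yates(ContingencyTable(0, 0, 10, 20))


class TestBinomialLookup:
    def test_certain_event_has_probability_one(self):
        assert binomial_lookup(0, 7, 0.3) == 1.0

    def test_monotone_in_k_and_p0(self):
        ps = [binomial_lookup(k, 10, 0.05) for k in range(11)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))
        qs = [binomial_lookup(3, 10, p0) for p0 in (0.01, 0.05, 0.2, 0.5)]
        assert all(x <= y for x, y in zip(qs, qs[1:]))

    def test_matches_exact_tail_sum(self):
        k, n, p0 = 3, 12, 0.07
        oracle = sum(stats.binom.pmf(i, n, p0) for i in range(k, n + 1))
        assert binomial_lookup(k, n, p0) == pytest.approx(oracle, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_lookup(5, 2, 0.1)
        with pytest.raises(ValueError):
            binomial_lookup(1, 2, 0.0)


class TestProportionCI:
    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = proportion_ci(0, 20)
        assert lo == 0.0
        assert hi > 0

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = proportion_ci(20, 20)
        assert hi == 1.0

    def test_wilson_formula_oracle(self):
        k, n = 52, 717
        z = stats.norm.isf(0.025)
        phat = k / n
        centre = (phat + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
        lo, hi = proportion_ci(k, n)
        assert lo == pytest.approx(centre - half, abs=1e-10)
        assert hi == pytest.approx(centre + half, abs=1e-10)
        assert lo < phat < hi

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)


class TestSensitivityGrid:
    def test_single_cell_equals_direct_composition(self):
        rng = np.random.default_rng(2)
        disc, look = rng.uniform(size=200), rng.uniform(size=200)
        grid = sensitivity_grid(disc, look, [0.1], [0.2])
        direct = enrich(disc, look, 0.1, 0.2)
        row = grid.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (
            direct.table.a, direct.table.b, direct.table.c, direct.table.d
        )
        assert row["chi2_p"] == direct.chi2_p

    def test_grid_cardinality(self):
        rng = np.random.default_rng(2)
        disc, look = rng.uniform(size=50), rng.uniform(size=50)
        grid = sensitivity_grid(disc, look, [0.1, 0.5], [0.2, 0.6])
        assert len(grid) == 4

    def test_zero_margin_cell_flagged_not_fatal(self):
        disc = [0.5] * 5 + [0.95] * 5
        look = [0.5] * 5 + [0.95] * 5
        grid = sensitivity_grid(disc, look, [1e-6, 0.9], [0.9])
        assert not grid.loc[grid["disc_thresh"] == 1e-6, "valid"].iloc[0]
        assert grid.loc[grid["disc_thresh"] == 0.9, "valid"].iloc[0]

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_grid([0.5], [0.5], [], [0.05])


class TestQQ:
    def test_uniform_grid_sits_on_diagonal_with_unit_lambda(self):
        n = 99
        p = np.arange(1, n + 1) / (n + 1.0)
        qq = qq_points(p)
        np.testing.assert_allclose(qq.points["observed"], qq.points["expected"], atol=1e-12)
        assert qq.lambda_gc == pytest.approx(1.0, abs=1e-12)

    def test_lambda_at_median_p_half(self):
        qq = qq_points([0.5, 0.5, 0.5])
        oracle = stats.chi2.isf(0.5, 1) / stats.chi2.ppf(0.5, 1)
        assert qq.lambda_gc == pytest.approx(oracle, abs=1e-12)
        assert qq.lambda_gc == pytest.approx(1.0, abs=1e-12)

    def test_enriched_tail_lifts_top_ranks(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(size=2000), np.full(20, 1e-8)])
        qq = qq_points(p)
        top = qq.points.iloc[0]  # smallest p (largest -log10) comes first
        assert top["observed"] > top["expected"]
        assert qq.lambda_gc > 0.9

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            qq_points([])
        with pytest.raises(ValueError):
            qq_points([0.0, 0.5])
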