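import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstrait.synthetic import (
    GeneratorConfig,
    generate_casecontrol,
    generate_paired_sumstats,
    generate_pathway_fixture,
    null_config,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw, msg",
        [
            ({"rho_ld": 1.0}, "rho_ld"),
            ({"maf_range": (0.0, 0.5)}, "maf_lo"),
            ({"pi_shared": 0.6, "pi_a": 0.3, "pi_b": 0.3}, "pi_shared"),
            ({"rho_effect": -1.5}, "rho_effect"),
            ({"n_a": 1}, "sample sizes"),
        ],
    )
    def test_invalid_config_names_violated_invariant(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            GeneratorConfig(**kw).validate()

    def test_n_snps_is_blocks_times_block_size(self):
        assert GeneratorConfig(n_blocks=10, block_size=5).n_snps == 50


class TestPairedSumstats:
    def test_pure_null_pvalues_are_uniform(self):
        # within-block LD correlates neighbours, so test the independent
        # block tags, pooled over several replicates
        p_a, p_b = [], []
        for seed in range(1, 6):
            sim = generate_paired_sumstats(null_config(n_snps=10_000, seed=seed))
            tag = sim.truth["TAG"].to_numpy()
            p_a.extend(sim.table_a.df.loc[tag, "P"])
            p_b.extend(sim.table_b.df.loc[tag, "P"])
            assert not sim.truth["CAUSAL_A"].any()
        assert stats.kstest(p_a, "uniform").pvalue > 0.01
        assert stats.kstest(p_b, "uniform").pvalue > 0.01

    def test_perfect_negative_effect_correlation_gives_discordant_signs(self):
        cfg = GeneratorConfig(n_blocks=200, block_size=5, pi_shared=0.25,
                              rho_effect=-1.0, seed=2)
        sim = generate_paired_sumstats(cfg)
        shared = sim.truth[sim.truth["CAUSAL_A"] & sim.truth["CAUSAL_B"]]
        assert len(shared) >= 30
        signs = np.sign(shared["BETA_A_TRUE"]) == np.sign(shared["BETA_B_TRUE"])
        assert not signs.any()

    def test_same_seed_reproduces_tables_exactly(self):
        cfg = GeneratorConfig(n_blocks=20, block_size=10, seed=3)
        s1 = generate_paired_sumstats(cfg)
        s2 = generate_paired_sumstats(cfg)
        pd.testing.assert_frame_equal(s1.table_a.df, s2.table_a.df)
        pd.testing.assert_frame_equal(s1.table_b.df, s2.table_b.df)
        pd.testing.assert_frame_equal(s1.truth, s2.truth)

    def test_planted_effects_shift_tag_zscores(self):
        cfg = GeneratorConfig(n_blocks=100, block_size=5, pi_a=0.5,
                              effect_sd_a=0.05, seed=4)
        sim = generate_paired_sumstats(cfg)
        df = sim.table_a.df
        z = (df["BETA"] / df["SE"]).to_numpy()
        causal = (sim.truth["BETA_A_TRUE"] != 0).to_numpy()
        tag_null = (sim.truth["TAG"] & ~causal).to_numpy()
        assert np.mean(np.abs(z[causal])) > 2 * np.mean(np.abs(z[tag_null]))

    def test_ld_pairs_follow_block_decay(self):
        cfg = GeneratorConfig(n_blocks=4, block_size=6, rho_ld=0.8,
                              ld_r2_floor=0.01, seed=5)
        sim = generate_paired_sumstats(cfg)
        assert sim.ld.r2("rs1", "rs2") == pytest.approx(0.8**2)
        assert sim.ld.r2("rs1", "rs3") == pytest.approx(0.8**4)
        assert sim.ld.r2("rs6", "rs7") == 0.0  # different blocks

    def test_zscore_correlation_matches_ld_decay(self):
        """Empirical correlation of within-block z-scores over many replicates
        reproduces the rho^|i-j| decay the generator claims."""
        n_rep, bs, rho = 2000, 4, 0.8
        z = np.empty((n_rep, bs))
        for i in range(n_rep):
            cfg = null_config(n_snps=bs, block_size=bs, rho_ld=rho, seed=10_000 + i)
            df = generate_paired_sumstats(cfg).table_a.df
            z[i] = (df["BETA"] / df["SE"]).to_numpy()
        emp = np.corrcoef(z.T)
        expect = rho ** np.abs(np.subtract.outer(np.arange(bs), np.arange(bs)))
        assert np.max(np.abs(emp - expect)) < 3.0 / np.sqrt(n_rep) + 0.02

    def test_ambiguous_fraction_produces_palindromic_alleles(self):
        cfg = null_config(n_snps=1000, seed=6, frac_ambiguous=0.2)
        df = generate_paired_sumstats(cfg).table_a.df
        pal = ((df["EA"] == "A") & (df["OA"] == "T")) | ((df["EA"] == "T") & (df["OA"] == "A")) \
            | ((df["EA"] == "C") & (df["OA"] == "G")) | ((df["EA"] == "G") & (df["OA"] == "C"))
        assert 0.1 < pal.mean() < 0.3


def effects_frame(n, eaf=0.3, beta=0.0):
    return pd.DataFrame(
        {"SNP": [f"s{i}" for i in range(n)], "EAF": eaf,
         "BETA_TRUE": [beta] + [0.0] * (n - 1) if np.ndim(beta) == 0 else beta}
    )


class TestCaseControl:
    def test_null_effects_leave_frequencies_indistinguishable(self):
        eff = effects_frame(50, beta=0.0)
        dos, status = generate_casecontrol(eff, 300, 300, seed=7)
        case_f = dos[status == 1].mean() / 2
        ctrl_f = dos[status == 0].mean() / 2
        # binomial sampling error of a frequency difference at n=300
        se = np.sqrt(2 * 0.3 * 0.7 / (2 * 300))
        assert np.all(np.abs(case_f - ctrl_f) < 4 * se)

    def test_large_effect_snp_enriched_in_cases(self):
        eff = effects_frame(5, beta=0.8)  # only the first SNP is causal
        dos, status = generate_casecontrol(eff, 400, 400, prevalence=0.1, seed=8)
        case_f = dos[status == 1].iloc[:, 0].mean() / 2
        ctrl_f = dos[status == 0].iloc[:, 0].mean() / 2
        assert case_f > ctrl_f + 0.02

    def test_seed_determinism(self):
        eff = effects_frame(10, beta=0.2)
        d1, s1 = generate_casecontrol(eff, 50, 50, seed=9)
        d2, s2 = generate_casecontrol(eff, 50, 50, seed=9)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_series_equal(s1, s2)

    def test_quota_shapes_and_status(self):
        eff = effects_frame(3)
        dos, status = generate_casecontrol(eff, 20, 30, seed=10)
        assert dos.shape == (50, 3)
        assert int(status.sum()) == 20

    def test_impossible_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_casecontrol(effects_frame(2), 10, 10, prevalence=1.5)
        big = effects_frame(2, beta=[0.9, 0.9])
        with pytest.raises(ValueError, match="liability variance"):
            generate_casecontrol(big, 10, 10)

    def test_unreachable_quota_errors_after_bounded_attempts(self):
        eff = effects_frame(2)
        with pytest.raises(RuntimeError, match="quota"):
            generate_casecontrol(eff, 5000, 10, prevalence=0.001,
                                 batch_size=100, max_batches=3)


class TestPathwayFixture:
    def test_cardinalities_as_configured(self):
        genes, catalog, gene_set = generate_pathway_fixture(
            n_genes=80, n_pathways=6, planted_pathway_size=12,
            planted_overlap=4, gene_set_size=10, seed=11,
        )
        assert len(genes) == 80
        assert len(catalog) == 6
        assert len(gene_set) == 10
        planted = catalog.pathways["planted_pathway"]
        assert len(planted & set(gene_set)) == 4

    def test_full_overlap_gives_closed_form_fisher(self):
        from crosstrait.pathways import overrep_test

        genes, catalog, gene_set = generate_pathway_fixture(
            n_genes=30, n_pathways=2, planted_pathway_size=5,
            planted_overlap=5, gene_set_size=5, seed=12,
        )
        results, _ = overrep_test(gene_set, catalog)
        planted = next(r for r in results if r.pathway == "planted_pathway")
        oracle = stats.hypergeom.sf(4, 30, 5, 5)
        assert planted.fisher_p == pytest.approx(oracle, rel=1e-10)

    def test_zero_overlap_fisher_approximately_uniform(self):
        ps = []
        for seed in range(60):
            _, catalog, gene_set = generate_pathway_fixture(
                n_genes=200, n_pathways=3, planted_pathway_size=20,
                planted_overlap=0, gene_set_size=15, seed=100 + seed,
            )
            from crosstrait.pathways import overrep_test

            results, _ = overrep_test(gene_set, catalog)
            planted = next(r for r in results if r.pathway == "planted_pathway")
            ps.append(planted.fisher_p)
        # a null discrete test is conservative, never anti-conservative
        assert np.mean(np.array(ps) < 0.05) <= 0.1

    def test_overlap_bounds_enforced(self):
        with pytest.raises(ValueError):
            generate_pathway_fixture(planted_pathway_size=5, planted_overlap=6)
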