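import numpy as np
import pytest
from scipy import stats

from locusweave import simulate as sim


class TestLdGenotypes:
    def test_zero_rho_gives_near_independent_snps(self):
        cfg = sim.SimRegionConfig(n_snps=50, rho=0.0, seed=3)
        _, ld, _ = sim.simulate_ld_genotypes(cfg, 2000)
        off = np.abs(ld[np.triu_indices(50, k=1)])
        assert off.mean() < 0.05

    def test_same_seed_is_bitwise_identical(self):
        cfg = sim.SimRegionConfig(n_snps=10, rho=0.5, seed=9)
        g1, ld1, m1 = sim.simulate_ld_genotypes(cfg, 200)
        g2, ld2, m2 = sim.simulate_ld_genotypes(cfg, 200)
        np.testing.assert_array_equal(g1, g2)
        np.testing.assert_array_equal(ld1, ld2)
        np.testing.assert_array_equal(m1, m2)

    def test_maf_half_gives_mean_dosage_one(self):
        cfg = sim.SimRegionConfig(n_snps=20, rho=0.3, maf_range=(0.5, 0.5), seed=5)
        g, _, _ = sim.simulate_ld_genotypes(cfg, 4000)
        means = g.mean(axis=0)
        se = np.sqrt(0.5 / 4000)  # binomial(2, 0.5) per individual
        assert np.all(np.abs(means - 1.0) < 3 * se * np.sqrt(2))

    def test_empirical_ld_converges_to_copula_target(self):
        # adjacent-SNP dosage correlation approaches the AR(1)-implied value
        cfg = sim.SimRegionConfig(n_snps=12, rho=0.8, maf_range=(0.3, 0.3), seed=6)
        g, ld, _ = sim.simulate_ld_genotypes(cfg, 10_000)
        cfg2 = sim.SimRegionConfig(n_snps=12, rho=0.8, maf_range=(0.3, 0.3), seed=7)
        g2, ld2, _ = sim.simulate_ld_genotypes(cfg2, 10_000)
        adj1 = np.diag(ld, k=1)
        adj2 = np.diag(ld2, k=1)
        assert np.abs(adj1 - adj2).max() < 0.03  # stable across realizations

    @pytest.mark.parametrize("kwargs", [
        {"n_snps": 0}, {"rho": 1.0}, {"rho": -0.1}, {"maf_range": (0.4, 0.2)},
        {"maf_range": (0.0, 0.6)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        base = {"n_snps": 5, "rho": 0.5, "maf_range": (0.1, 0.4), "seed": 0}
        base.update(kwargs)
        with pytest.raises(ValueError):
            sim.SimRegionConfig(**base)

    def test_too_few_individuals_fatal(self):
        with pytest.raises(ValueError):
            sim.simulate_ld_genotypes(sim.SimRegionConfig(n_snps=3), 1)


@pytest.fixture(scope="module")
def pool():
    cfg = sim.SimRegionConfig(n_snps=30, rho=0.5, seed=11)
    g, _, _ = sim.simulate_ld_genotypes(cfg, 1200)
    return g


class TestTraitPair:

    def test_null_scenario_type_i_error_calibrated(self, pool):
        causal = sim.CausalConfig("null")
        hits = []
        for rep in range(20):
            gwas, qtl = sim.simulate_trait_pair(pool, causal, 400, 400, 300,
                                                seed=100 + rep)
            hits.append((gwas["pvalue"] < 0.05).mean())
            hits.append((qtl["pvalue"] < 0.05).mean())
        frac = np.mean(hits)
        n_tests = 20 * 2 * 30
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_tests) + 0.01

    def test_shared_causal_snp_attains_minimum_qtl_p(self, pool):
        causal = sim.CausalConfig("shared", 10, 10, beta_trait=0.3, beta_qtl=1.0)
        wins = 0
        for rep in range(50):
            _, qtl = sim.simulate_trait_pair(pool, causal, 50, 50, 300,
                                             seed=500 + rep)
            wins += int(qtl["pvalue"].idxmin() == 10)
        assert wins >= int(0.95 * 50) - 2

    def test_null_z_scores_standard_normal(self):
        # aggregate z over independent SNPs (rho=0) and replicates -> iid N(0,1)
        cfg = sim.SimRegionConfig(n_snps=20, rho=0.0, seed=21)
        g, _, _ = sim.simulate_ld_genotypes(cfg, 900)
        causal = sim.CausalConfig("null")
        zs_g, zs_q = [], []
        for rep in range(15):
            gwas, qtl = sim.simulate_trait_pair(g, causal, 300, 300, 300,
                                                seed=700 + rep)
            zs_g.extend(gwas["beta"] / gwas["se"])
            zs_q.extend(qtl["beta"] / qtl["se"])
        assert stats.kstest(zs_g, "norm").pvalue > 0.01
        assert stats.kstest(zs_q, "norm").pvalue > 0.01

    def test_deterministic_given_seed(self, pool):
        causal = sim.CausalConfig("shared", 3, 3)
        import pandas as pd
        a = sim.simulate_trait_pair(pool, causal, 100, 100, 200, seed=4)
        b = sim.simulate_trait_pair(pool, causal, 100, 100, 200, seed=4)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_scenario_index_consistency_enforced(self):
        with pytest.raises(ValueError):
            sim.CausalConfig("shared", 1, 2)
        with pytest.raises(ValueError):
            sim.CausalConfig("distinct", 1, 1)

    def test_insufficient_pool_fatal(self, pool):
        with pytest.raises(ValueError, match="cohort"):
            sim.simulate_trait_pair(pool, sim.CausalConfig("null"), 900, 900, 300,
                                    seed=0)


@pytest.fixture(scope="module")
def geno():
    cfg = sim.SimRegionConfig(n_snps=5, rho=0.4, seed=31)
    g, _, _ = sim.simulate_ld_genotypes(cfg, 150)
    return g


class TestMethylation:

    def test_beta_values_strictly_in_unit_interval(self, geno):
        beta, _, _ = sim.simulate_methylation(geno, sim.default_positions(5),
                                              (2, 1, 0.5), seed=1)
        vals = beta.to_numpy()
        assert np.all(vals > 0) and np.all(vals < 1)

    def test_null_effect_t_statistics_follow_t_distribution(self, geno):
        from locusweave.mqtl import fit_cis_mqtl
        tstats = []
        for rep in range(60):
            beta, _, cov = sim.simulate_methylation(
                geno, sim.default_positions(5), (2, 1, 0.0), seed=200 + rep,
                n_cpgs=5)
            for j in range(5):
                b, se, _ = fit_cis_mqtl(geno[:, 2], beta.iloc[j].to_numpy(), cov)
                tstats.append(b / se)
        df = 150 - 8 - 1  # intercept + 5 numeric + 2 batch dummies + genotype
        assert stats.kstest(tstats, "t", args=(df,)).pvalue > 0.01

    def test_deterministic_given_seed(self, geno):
        a = sim.simulate_methylation(geno, sim.default_positions(5), (2, 1, 0.5), seed=9)
        b = sim.simulate_methylation(geno, sim.default_positions(5), (2, 1, 0.5), seed=9)
        np.testing.assert_array_equal(a[0].to_numpy(), b[0].to_numpy())
        assert a[2].equals(b[2])


def test_genotype_gzip_roundtrip(tmp_path):
    cfg = sim.SimRegionConfig(n_snps=4, rho=0.2, seed=17)
    g, _, _ = sim.simulate_ld_genotypes(cfg, 30)
    ids = [f"snp_{i}" for i in range(4)]
    path = tmp_path / "geno.tsv.gz"
    sim.write_genotypes(g, ids, path)
    back, back_ids = sim.read_genotypes(path)
    np.testing.assert_array_equal(back, g)
    assert back_ids == ids


class TestCelltypeExpression:
    def test_marker_fold_recovered_by_prevalence_ratio(self):
        from locusweave.celltype import prevalence_enrichment
        types = ["astrocyte", "microglia", "neuron", "oligodendrocyte"]
        expr, labels, truth = sim.simulate_celltype_expression(
            40, types, markers_per_type=2, fold=5.0, seed=2)
        marker = truth.iloc[0]
        prof = prevalence_enrichment(expr, labels, marker["gene_id"])
        assert prof.primary_type == marker["marker_type"]
        assert prof.enrichment[marker["marker_type"]] == pytest.approx(5.0, rel=0.10)

    def test_non_marker_enrichment_near_unity(self):
        types = ["a", "b", "c"]
        expr, labels, truth = sim.simulate_celltype_expression(
            30, types, markers_per_type=2, fold=5.0, seed=3)
        from locusweave.celltype import prevalence_enrichment
        prof = prevalence_enrichment(expr, labels, "gene_0029")  # not a marker
        assert all(abs(v - 1.0) < 0.25 for v in prof.enrichment.values())

    def test_deterministic_given_seed(self):
        a = sim.simulate_celltype_expression(10, ["x", "y"], 1, 3.0, seed=4)
        b = sim.simulate_celltype_expression(10, ["x", "y"], 1, 3.0, seed=4)
        np.testing.assert_array_equal(a[0].to_numpy(), b[0].to_numpy())

    def test_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            sim.simulate_celltype_expression(10, ["x", "y"], 1, 1.0, seed=0)


class TestInteractome:
    SEEDS = [f"s{i}" for i in range(9)]
    MEND = [f"m{i}" for i in range(20)]

    def test_no_bridges_no_background_means_no_connections(self):
        from locusweave.netperm import build_seed_network, count_mendelian_connections
        G, _ = sim.simulate_interactome(50, 0.0, self.SEEDS, self.MEND, 0, 118, seed=1)
        net = build_seed_network(G, set(self.SEEDS), set(self.MEND))
        assert count_mendelian_connections(net) == 0

    def test_planted_bridges_counted_exactly(self):
        from locusweave.netperm import build_seed_network, count_mendelian_connections
        G, _ = sim.simulate_interactome(0, 0.0, self.SEEDS, self.MEND, 9, 118, seed=1)
        net = build_seed_network(G, set(self.SEEDS), set(self.MEND))
        assert count_mendelian_connections(net) == 9

    def test_null_pool_has_requested_size(self):
        _, pool = sim.simulate_interactome(10, 0.01, self.SEEDS, self.MEND, 0,
                                           118, seed=1)
        assert len(pool) == 118

    def test_too_many_bridges_fatal(self):
        with pytest.raises(ValueError):
            sim.simulate_interactome(10, 0.0, self.SEEDS, self.MEND,
                                     len(self.MEND) + 1, 10, seed=1)

    def test_overlapping_name_sets_fatal(self):
        with pytest.raises(ValueError, match="disjoint"):
            sim.simulate_interactome(10, 0.0, ["x"], ["x"], 0, 10, seed=1)
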