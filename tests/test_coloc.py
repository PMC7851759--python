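import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locusweave import coloc
from locusweave.sumstats import SUMSTAT_COLUMNS
from tests.conftest import make_sumstats


def enumeration_posteriors(labf1, labf2, priors=coloc.PriorConfig()):
    """Independent oracle: exhaustively enumerate causal configurations.

    Under the one-causal-variant-per-trait assumption, every configuration is
    either the null, one SNP causal for trait 1 only, one for trait 2 only,
    an ordered pair of different SNPs, or one shared SNP.  Masses are the
    per-configuration prior times the product of the relevant ABFs.
    """
    abf1 = np.exp(np.asarray(labf1, dtype=float))
    abf2 = np.exp(np.asarray(labf2, dtype=float))
    n = len(abf1)
    h = np.zeros(5)
    h[0] = 1.0
    for i in range(n):
        h[1] += priors.p1 * abf1[i]
        h[2] += priors.p2 * abf2[i]
        h[4] += priors.p12 * abf1[i] * abf2[i]
        for j in range(n):
            if i != j:
                h[3] += priors.p1 * priors.p2 * abf1[i] * abf2[j]
    return h / h.sum()


class TestWakefieldLogAbf:
    def test_zero_effect_reduces_to_closed_form(self):
        se, sd = 0.2, 0.15
        r = sd**2 / (sd**2 + se**2)
        out = coloc.wakefield_log_abf(0.0, se, sd)
        assert out == pytest.approx(0.5 * np.log(1 - r))
        assert out < 0

    def test_vanishing_prior_sd_gives_no_evidence(self):
        assert coloc.wakefield_log_abf(0.3, 0.1, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_value(self):
        # r = 0.0225/0.0325, z = 3: ABF = exp(0.5 ln(1-r) + r z^2 / 2) ~ 12.50
        assert np.exp(coloc.wakefield_log_abf(0.3, 0.1, 0.15)) == pytest.approx(
            12.504, abs=5e-3)

    def test_nonpositive_se_fatal(self):
        with pytest.raises(ValueError):
            coloc.wakefield_log_abf(0.3, 0.0, 0.15)


class TestColocPosteriors:
    def test_single_snp_region_has_exactly_zero_pph3(self):
        post = coloc.coloc_posteriors([3.0], [2.0])
        assert post.pph3 == 0.0
        assert post.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_snp_worked_example(self):
        labf = np.array([np.log(10.0), 0.0])
        post = coloc.coloc_posteriors(labf, labf)
        assert post.pph4 == pytest.approx(1.007e-3, rel=1e-3)
        assert post.pph3 == pytest.approx(1.99e-7, rel=1e-2)
        assert post.pph0 > 0.99

    def test_swapping_traits_swaps_pph1_pph2_only(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 3, 5), rng.normal(0, 3, 5)
        p = coloc.coloc_posteriors(a, b)
        q = coloc.coloc_posteriors(b, a)
        assert p.pph1 == pytest.approx(q.pph2)
        assert p.pph2 == pytest.approx(q.pph1)
        for attr in ("pph0", "pph3", "pph4"):
            assert getattr(p, attr) == pytest.approx(getattr(q, attr))

    def test_matches_enumeration_oracle_on_fuzzed_regions(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 7))
            labf1 = rng.normal(0, 5, n)
            labf2 = rng.normal(0, 5, n)
            post = coloc.coloc_posteriors(labf1, labf2)
            oracle = enumeration_posteriors(labf1, labf2)
            np.testing.assert_allclose(post.as_array(), oracle, atol=1e-10)

    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=12),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_posteriors_always_sum_to_one(self, labf1, seed):
        labf2 = np.random.default_rng(seed).normal(0, 10, len(labf1))
        post = coloc.coloc_posteriors(np.array(labf1), labf2)
        assert post.as_array().sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(post.as_array() >= 0)
        assert post.per_snp_h4.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pph4_monotone_in_p12(self, rng):
        labf1, labf2 = rng.normal(0, 4, 8), rng.normal(0, 4, 8)
        p12s = [1e-7, 1e-6, 1e-5, 5e-5]
        vals = [coloc.coloc_posteriors(labf1, labf2,
                                       coloc.PriorConfig(p12=p)).pph4
                for p in p12s]
        assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_per_snp_h4_invariant_to_common_shift(self, rng):
        labf1, labf2 = rng.normal(0, 4, 6), rng.normal(0, 4, 6)
        a = coloc.coloc_posteriors(labf1, labf2).per_snp_h4
        b = coloc.coloc_posteriors(labf1 + 7.0, labf2 + 7.0).per_snp_h4
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_length_mismatch_and_empty_fatal(self):
        with pytest.raises(ValueError):
            coloc.coloc_posteriors([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            coloc.coloc_posteriors([], [])


class TestPriorConfig:
    def test_defaults_match_standard_coloc_priors(self):
        p = coloc.PriorConfig()
        assert (p.p1, p.p2, p.p12) == (1e-4, 1e-4, 1e-5)

    @pytest.mark.parametrize("kwargs", [
        {"p12": 2e-4},             # p12 > min(p1, p2)
        {"p12": 0.0},
        {"p1": 0.5, "p2": 0.5, "p12": 0.1},
        {"prior_sd_quant": 0.0},
    ])
    def test_invalid_priors_rejected(self, kwargs):
        with pytest.raises(ValueError):
            coloc.PriorConfig(**kwargs)


class TestColocalizeFeature:
    def _frames(self, beta_g, beta_q, se=0.05):
        gwas = make_sumstats([{"beta": b, "se": se} for b in beta_g])
        qtl = make_sumstats([{"beta": b, "se": se} for b in beta_q])
        return gwas, qtl

    def test_trait_type_selects_prior_sd(self):
        gwas, qtl = self._frames([0.3, 0.0], [0.5, 0.0])
        res = coloc.colocalize_feature(gwas, qtl, feature_id="G")
        labf_cc = coloc.wakefield_log_abf(gwas["beta"], gwas["se"], 0.15)
        labf_q = coloc.wakefield_log_abf(qtl["beta"], qtl["se"], 0.2)
        expected = coloc.coloc_posteriors(labf_cc, labf_q)
        np.testing.assert_allclose(res.posterior.as_array(), expected.as_array())

    def test_top_snv_is_argmax_h4_contribution(self):
        gwas, qtl = self._frames([0.0, 0.4, 0.0], [0.0, 0.6, 0.0])
        res = coloc.colocalize_feature(gwas, qtl, feature_id="G")
        assert res.posterior.top_snv == "rs2"

    def test_top_snv_tie_broken_by_lowest_position(self):
        gwas, qtl = self._frames([0.4, 0.4], [0.6, 0.6])
        res = coloc.colocalize_feature(gwas, qtl, feature_id="G")
        assert res.posterior.top_snv == "rs1"

    def test_single_snp_still_computes_with_warning(self, caplog):
        gwas, qtl = self._frames([0.4], [0.6])
        with caplog.at_level("WARNING"):
            res = coloc.colocalize_feature(gwas, qtl, feature_id="G")
        assert res.posterior.pph3 == 0.0


class TestClassifySplicing:
    def _result(self, pph3, pph4, level="gene", fid="G"):
        per = np.array([1.0])
        rest = max(1.0 - pph3 - pph4, 0.0)
        post = coloc.ColocPosterior(rest, 0, 0, pph3, pph4, 1, per)
        return coloc.FeatureColocResult(feature_id=fid, posterior=post,
                                        feature_level=level)

    def test_exon_coloc_with_gene_level_evidence_against_is_splicing(self):
        # the published ZRANB3-style pattern: exon PPH4 0.93, gene PPH3 0.20 > PPH4 0.07
        gene = self._result(0.20, 0.07)
        exon = self._result(0.06, 0.93, level="exon")
        assert coloc.classify_splicing(gene, [exon]) == "splicing"

    def test_subthreshold_exon_is_none(self):
        gene = self._result(0.5, 0.1)
        exon = self._result(0.1, 0.74, level="exon")
        assert coloc.classify_splicing(gene, [exon]) == "none"

    def test_gene_level_colocalization_takes_precedence(self):
        gene = self._result(0.05, 0.80)
        exon = self._result(0.02, 0.95, level="exon")
        assert coloc.classify_splicing(gene, [exon]) == "expression"

    def test_exon_threshold_inclusive_at_0_75(self):
        gene = self._result(0.30, 0.10)
        exon = self._result(0.05, 0.75, level="exon")
        assert coloc.classify_splicing(gene, [exon]) == "splicing"


def test_results_frame_has_expected_columns():
    post = coloc.ColocPosterior(0.9, 0.02, 0.02, 0.02, 0.04, 3,
                                np.ones(3) / 3, top_snv="rs1")
    res = coloc.FeatureColocResult("G", post, tissue="putamen", dataset="sim")
    df = coloc.results_to_frame([res], {"G": "none"})
    assert set(SUMSTAT_COLUMNS).isdisjoint(df.columns)  # feature table, not sumstats
    for col in ("feature_id", "pph0", "pph4", "top_snv", "classification"):
        assert col in df.columns
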