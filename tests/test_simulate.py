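"""Ground-truth synthetic study generator."""

import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import kstest

import gxekit as g
from gxekit.errors import AlignmentError, ConfigurationError
from gxekit.simulate import MISSING


class TestGenerateGenotypes:
    def test_allele_frequencies_recovered_without_ld(self):
        cfg = g.SimulationConfig(n_individuals=4000, n_blocks=30, snps_per_block=2,
                                 within_block_rho=0.0, missing_rate=0.0, n_causal=5, seed=2)
        geno = g.generate_genotypes(cfg)
        freq = geno.allele_freq()
        maf = geno.variants["maf"].to_numpy()
        se = np.sqrt(maf * (1 - maf) / (2 * cfg.n_individuals))
        assert (np.abs(freq - maf) < 3.5 * se).mean() > 0.98  # ~3 SE binomial bound

    def test_degenerate_1x1(self):
        cfg = g.SimulationConfig(n_individuals=1, n_blocks=1, snps_per_block=1,
                                 n_causal=1, missing_rate=0.0, seed=0)
        geno = g.generate_genotypes(cfg)
        assert geno.dosages.shape == (1, 1)
        assert geno.dosages[0, 0] in (0, 1, 2)

    def test_same_seed_bit_identical(self):
        cfg = g.SimulationConfig(n_individuals=100, seed=9)
        a, b = g.generate_genotypes(cfg), g.generate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)

    def test_block_geometry_respects_clump_window(self):
        cfg = g.SimulationConfig(n_individuals=10, n_blocks=3, snps_per_block=50,
                                 n_causal=5, seed=1)
        v = g.generate_genotypes(cfg).variants
        for b in range(3):
            pos = v[v["block"] == b]["pos"]
            assert pos.max() - pos.min() < 250_000          # block spans < window
        starts = v.groupby("block")["pos"].min().to_numpy()
        ends = v.groupby("block")["pos"].max().to_numpy()
        assert (starts[1:] - ends[:-1] > 250_000).all()     # blocks > window apart

    def test_within_block_correlation_increases_with_rho(self):
        def adj_corr(rho):
            cfg = g.SimulationConfig(n_individuals=3000, n_blocks=10, snps_per_block=4,
                                     within_block_rho=rho, missing_rate=0.0, n_causal=5, seed=4)
            d = g.generate_genotypes(cfg).dosages.astype(float)
            cs = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
                  for j in range(0, 40, 4) for j in (j, j + 1, j + 2)]
            return np.mean(cs)
        assert adj_corr(0.0) == pytest.approx(0.0, abs=0.05)
        assert 0.2 < adj_corr(0.5) < adj_corr(0.9)

    def test_missingness_rate(self):
        cfg = g.SimulationConfig(n_individuals=2000, missing_rate=0.05, seed=3)
        geno = g.generate_genotypes(cfg)
        assert (geno.dosages == MISSING).mean() == pytest.approx(0.05, abs=0.005)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            g.SimulationConfig(n_individuals=0)
        with pytest.raises(ConfigurationError):
            g.SimulationConfig(maf_range=(0.3, 0.2))
        with pytest.raises(ConfigurationError):
            g.SimulationConfig(n_blocks=2, snps_per_block=2, n_causal=10)


class TestGenerateSumstats:
    def test_huge_effective_n_recovers_true_betas(self):
        cfg = g.SimulationConfig(n_individuals=200, gwas_n_effective=10**8,
                                 n_causal=40, causal_beta_sd=0.2, seed=6)
        geno = g.generate_genotypes(cfg)
        truth = g.make_ground_truth(geno, cfg)
        ss = g.generate_sumstats(geno, truth, cfg)
        assert np.abs(ss["beta"].to_numpy() - truth.causal_betas).max() < 1e-3

    def test_null_pvalues_uniform(self):
        # 1,000 independent null variants -> p-values ~ U(0,1)
        cfg = g.SimulationConfig(n_individuals=50, n_blocks=500, snps_per_block=2,
                                 within_block_rho=0.0, n_causal=1, causal_beta_sd=0.0,
                                 seed=8)
        geno = g.generate_genotypes(cfg)
        truth = g.make_ground_truth(geno, cfg)
        ss = g.generate_sumstats(geno, truth, cfg)
        assert kstest(ss["pvalue"], "uniform").pvalue > 0.01

    def test_causal_variants_more_significant_in_expectation(self):
        cfg = g.SimulationConfig(n_individuals=200, n_causal=40, causal_beta_sd=0.3, seed=6)
        geno = g.generate_genotypes(cfg)
        truth = g.make_ground_truth(geno, cfg)
        ss = g.generate_sumstats(geno, truth, cfg)
        causal = truth.causal_betas != 0
        assert np.median(np.log10(ss["pvalue"][causal])) < np.median(np.log10(ss["pvalue"][~causal]))

    def test_pvalue_consistent_with_beta_and_se(self):
        from scipy.stats import norm
        cfg = g.SimulationConfig(n_individuals=100, seed=12)
        geno = g.generate_genotypes(cfg)
        truth = g.make_ground_truth(geno, cfg)
        ss = g.generate_sumstats(geno, truth, cfg)
        expect = 2 * norm.sf(np.abs(ss["beta"] / ss["se"]))
        np.testing.assert_allclose(ss["pvalue"], expect, atol=1e-12)

    def test_misaligned_truth_rejected(self):
        cfg = g.SimulationConfig(n_individuals=50, seed=1)
        geno = g.generate_genotypes(cfg)
        truth = g.make_ground_truth(geno, cfg)
        truth.causal_betas = truth.causal_betas[:-1]
        with pytest.raises(AlignmentError):
            g.generate_sumstats(geno, truth, cfg)

    def test_determinism(self):
        cfg = g.SimulationConfig(n_individuals=80, seed=5)
        geno = g.generate_genotypes(cfg)
        truth = g.make_ground_truth(geno, cfg)
        assert g.generate_sumstats(geno, truth, cfg).equals(g.generate_sumstats(geno, truth, cfg))


class TestGenerateCohort:
    def test_prevalence_matches_intercept_with_null_effects(self):
        n = 104_554
        cfg = g.SimulationConfig(
            n_individuals=n, n_blocks=2, snps_per_block=2, n_causal=2,
            missing_rate=0.0, extra_pollutants={},
            outcome_coefs=g.OutcomeCoefs(intercept=float(logit(0.0508)),
                                         prs_effect=0.0, slope_effect=0.0, interaction=0.0),
            seed=13)
        geno = g.generate_genotypes(cfg)
        truth = g.make_ground_truth(geno, cfg)
        _, slopes = g.generate_exposures(cfg, panel=False)
        cohort = g.generate_cohort(geno, truth, slopes, cfg)
        se = np.sqrt(0.0508 * (1 - 0.0508) / n)
        assert abs(cohort["t2d"].mean() - 0.0508) < 3 * se

    def test_prevalence_monotone_in_intercept(self):
        prevs = []
        for b0 in (-4.0, -3.0, -2.0):
            cfg = g.SimulationConfig(
                n_individuals=5000, n_blocks=2, snps_per_block=2, n_causal=2,
                missing_rate=0.0, extra_pollutants={},
                outcome_coefs=g.OutcomeCoefs(intercept=b0), seed=14)
            geno = g.generate_genotypes(cfg)
            truth = g.make_ground_truth(geno, cfg)
            _, slopes = g.generate_exposures(cfg, panel=False)
            g.generate_cohort(geno, truth, slopes, cfg)
            prevs.append(truth.achieved_prevalence)
        assert prevs[0] < prevs[1] < prevs[2]

    def test_determinism_and_alignment(self, small_study):
        cfg = small_study.config
        geno = small_study.genotypes
        truth = g.make_ground_truth(geno, cfg)
        _, slopes = g.generate_exposures(cfg, panel=False)
        a = g.generate_cohort(geno, truth, slopes, cfg)
        b = g.generate_cohort(geno, truth, slopes, cfg)
        assert a.equals(b)
        with pytest.raises(AlignmentError):
            g.generate_cohort(geno, truth, slopes.iloc[::-1].reset_index(drop=True), cfg)

    def test_implied_true_reri_consistent_with_evaluator(self, small_study):
        # the recorded value must equal the standard formula applied to the
        # cell odds of the true risks (re-derived here independently)
        truth = small_study.truth
        from gxekit.interaction import reri_from_odds_ratios
        from gxekit.simulate import implied_true_reri_from_risks
        z = (truth.true_prs - truth.true_prs.mean()) / truth.true_prs.std()
        oc = truth.true_outcome_coefs
        s = truth.true_slopes["pm25"].to_numpy()
        from scipy.special import expit
        lp = oc["intercept"] + oc["prs_effect"] * z + oc["slope_effect"] * s + oc["interaction"] * z * s
        val = implied_true_reri_from_risks(z, s, expit(lp))
        assert truth.implied_true_reri == pytest.approx(val, rel=1e-12)
        assert reri_from_odds_ratios(1.0, 1.0, 1.0) == 0.0
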