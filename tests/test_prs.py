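"""Genotype QC, allele alignment, LD clumping and PRS construction."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import gxekit as g
from gxekit.config import ClumpParams, QCParams
from gxekit.errors import DegenerateCategorizationError
from gxekit.prs import (
    AlignedEffects,
    align_alleles,
    hwe_exact_p,
    ld_clump,
    pihat_matrix,
    qc_individuals,
    qc_variants,
    quartile_categories,
    score,
    threshold_scan,
)
from gxekit.simulate import MISSING, GenotypeMatrix


def _matrix(dosages, positions=None, ref="A", alt="G", chrom="1"):
    dos = np.asarray(dosages, dtype=np.int8)
    n, m = dos.shape
    positions = positions if positions is not None else (1 + 500 * np.arange(m))
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "variant_id": [f"v{j}" for j in range(m)],
        "ref": [ref] * m if isinstance(ref, str) else ref,
        "alt": [alt] * m if isinstance(alt, str) else alt,
    })
    return GenotypeMatrix(dos, variants, [f"S{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-integer enumeration over heterozygote counts (independent route)."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = Fraction(math.factorial(n) * 2 ** h,
                              math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common))
    total = sum(weights.values())
    p_obs = weights[n_Aa] / total
    return float(sum(w for w in weights.values() if w / total <= p_obs) / total)


class TestHWE:
    def test_most_probable_configuration_gives_p_one(self):
        assert hwe_exact_p(0, 2, 0) == pytest.approx(1.0)

    def test_extreme_het_deficit(self):
        assert hwe_exact_p(50, 0, 50) < 1e-10

    def test_equilibrium_proportions_not_extreme(self):
        assert hwe_exact_p(25, 50, 25) > 0.5

    @pytest.mark.parametrize("counts", [(3, 5, 2), (10, 1, 9), (0, 7, 0), (12, 12, 1), (40, 20, 40)])
    def test_matches_integer_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(hwe_enumeration_oracle(*counts), rel=1e-9)

    @pytest.mark.parametrize("counts", [(3, 5, 2), (10, 1, 9), (25, 50, 25)])
    def test_allele_label_symmetry(self, counts):
        a, h, b = counts
        assert hwe_exact_p(a, h, b) == pytest.approx(hwe_exact_p(b, h, a), rel=1e-12)


# ---------------------------------------------------------------------------
# variant QC

class TestVariantQC:
    def test_equilibrium_variant_kept(self):
        dos = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)]).reshape(-1, 1)
        geno = _matrix(dos)
        y = np.tile([0, 1], 50)
        keep, report = qc_variants(geno, y)
        assert list(keep) == [0] and not report["excluded"].iloc[0]

    def test_monomorphic_excluded_by_maf(self):
        geno = _matrix(np.zeros((100, 1)))
        keep, report = qc_variants(geno, np.tile([0, 1], 50))
        assert keep.size == 0 and "maf" in report["reasons"].iloc[0]

    def test_three_percent_missing_excluded(self):
        dos = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)]).astype(np.int8)
        dos[:3] = MISSING  # 3% missing > 0.02
        keep, report = qc_variants(_matrix(dos.reshape(-1, 1)), np.tile([0, 1], 50))
        assert keep.size == 0 and "missingness" in report["reasons"].iloc[0]

    def test_hwe_stratified_thresholds(self):
        # gross het deficit in controls only; p < 1e-6 triggers the control threshold
        dos = np.concatenate([
            np.concatenate([np.zeros(30), np.full(30, 2)]),        # controls: no hets
            np.concatenate([np.zeros(15), np.ones(30), np.full(15, 2)]),  # cases: HWE
        ]).reshape(-1, 1)
        y = np.concatenate([np.zeros(60), np.ones(60)]).astype(int)
        keep, report = qc_variants(_matrix(dos), y)
        assert keep.size == 0 and "hwe_controls" in report["reasons"].iloc[0]


# ---------------------------------------------------------------------------
# individual QC

class TestIndividualQC:
    def test_duplicate_individual_detected_and_one_removed(self):
        cfg = g.SimulationConfig(n_individuals=60, n_blocks=1000, snps_per_block=2,
                                 within_block_rho=0.0, n_causal=5, missing_rate=0.0, seed=31)
        geno = g.generate_genotypes(cfg)
        geno.dosages[1] = geno.dosages[0]  # duplicate pair
        params = QCParams()
        ph = pihat_matrix(geno)
        assert ph[0, 1] > 0.9
        keep, report = qc_individuals(geno, params)
        flagged = report[report["reasons"].str.contains("pi-hat")]
        assert len(flagged) == 1 and flagged.index[0] in (0, 1)

    def test_unrelated_cohort_rarely_flagged(self):
        # i.i.d. genotypes: < 1% of pairs exceed pi-hat 0.2 at n=500, m=2000
        cfg = g.SimulationConfig(n_individuals=500, n_blocks=1000, snps_per_block=2,
                                 within_block_rho=0.0, n_causal=5, missing_rate=0.005, seed=32)
        geno = g.generate_genotypes(cfg)
        ph = pihat_matrix(geno)
        iu = np.triu_indices(500, k=1)
        assert (ph[iu] > 0.2).mean() < 0.01

    def test_heterozygosity_outlier_excluded(self):
        cfg = g.SimulationConfig(n_individuals=100, n_blocks=50, snps_per_block=2,
                                 within_block_rho=0.0, n_causal=5, missing_rate=0.0, seed=33)
        geno = g.generate_genotypes(cfg)
        geno.dosages[7] = 1  # heterozygous at every variant
        keep, report = qc_individuals(geno, QCParams(min_ibd_markers=10**6))
        assert report["excluded"].iloc[7]
        assert "heterozygosity" in report["reasons"].iloc[7]

    def test_shifted_subpopulation_caught_by_pcs(self):
        cfg = g.SimulationConfig(n_individuals=300, n_blocks=100, snps_per_block=2,
                                 within_block_rho=0.0, n_causal=5, missing_rate=0.0,
                                 subpop_fraction=0.01, subpop_shift=3.0, seed=34)
        geno = g.generate_genotypes(cfg)
        keep, report = qc_individuals(geno, QCParams(min_ibd_markers=10**6, pc_outlier_sd=4))
        assert report["reasons"].str.contains("PC outlier").any()


# ---------------------------------------------------------------------------
# allele alignment

class TestAlignAlleles:
    def _pair(self):
        rng = np.random.default_rng(40)
        dos = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
        geno = _matrix(dos, ref=["A", "A", "A", "A"], alt=["G", "G", "T", "G"])
        ss = pd.DataFrame({
            "chrom": "1", "pos": geno.variants["pos"],
            "variant_id": geno.variants["variant_id"],
            "effect_allele": ["G", "A", "T", "C"],   # as-is, swapped, ambiguous, incompatible
            "other_allele": ["A", "G", "A", "A"],
            "beta": [0.5, 0.5, 0.5, 0.5], "se": 0.1, "pvalue": 0.01,
        })
        return geno, ss

    def test_orientation_and_drops(self):
        geno, ss = self._pair()
        al = align_alleles(geno, ss)
        assert list(al.variant_idx) == [0, 1]
        assert list(al.flipped) == [False, True]
        assert set(al.dropped["reason"]) == {"strand-ambiguous (A/T or C/G)",
                                             "alleles C/A incompatible with A/G"}

    def test_swapped_alleles_scoring_identity(self):
        # sum(beta * (2 - G)) == sum((-beta) * G) + 2*sum(beta)
        geno, ss = self._pair()
        al = align_alleles(geno, ss)
        flipped_score = score(geno, al, subset_pos=np.array([1]))
        G = geno.dosages[:, 1].astype(float)
        np.testing.assert_allclose(flipped_score, (-0.5) * G + 2 * 0.5, atol=1e-12)


# ---------------------------------------------------------------------------
# clumping

def clump_oracle(pos, pvals, dosages, r2_cut, window_bp, threshold):
    """Brute-force reference: p-order, window and r2 rules applied literally."""
    cand = [j for j in range(len(pvals)) if pvals[j] <= threshold]
    cand.sort(key=lambda j: (pvals[j], pos[j], f"v{j}"))
    assigned, index_set = set(), []
    for j in cand:
        if j in assigned:
            continue
        assigned.add(j)
        index_set.append(j)
        for k in cand:
            if k in assigned or abs(pos[k] - pos[j]) > window_bp:
                continue
            r = np.corrcoef(dosages[:, j], dosages[:, k])[0, 1]
            if r * r >= r2_cut:
                assigned.add(k)
    return sorted(index_set)


def _random_instance(seed, m=30, n=120):
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    # induce correlated pairs: copy a neighbour with sparse perturbation
    for j in range(1, m, 3):
        mask = rng.random(n) < 0.15
        base[:, j] = np.where(mask, rng.integers(0, 3, size=n), base[:, j - 1])
    pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=m, replace=False))
    pvals = 10.0 ** rng.uniform(-10, 0, size=m)
    return base, pos, pvals


@pytest.mark.parametrize("seed", range(5))
def test_ld_clump_matches_bruteforce_oracle(seed):
    dos, pos, pvals = _random_instance(seed)
    geno = _matrix(dos, positions=pos)
    al = AlignedEffects(np.arange(30), np.zeros(30), np.zeros(30, bool), pvals,
                        pd.DataFrame(columns=["variant_id", "reason"]))
    got = ld_clump(geno, al, ClumpParams(), threshold=0.05)
    want = clump_oracle(pos, pvals, dos.astype(float), 0.1, 250_000, 0.05)
    assert list(got) == want


class TestClumpCases:
    def test_singleton_is_its_own_index(self):
        geno = _matrix(np.array([[0], [1], [2], [1]]))
        al = AlignedEffects(np.array([0]), np.array([0.1]), np.array([False]),
                            np.array([1e-9]), pd.DataFrame())
        assert list(ld_clump(geno, al, threshold=5e-8)) == [0]

    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        geno = _matrix(np.column_stack([col, col]), positions=[1000, 11_000])
        al = AlignedEffects(np.array([0, 1]), np.zeros(2), np.zeros(2, bool),
                            np.array([1e-8, 1e-9]), pd.DataFrame())
        assert list(ld_clump(geno, al, threshold=1e-6)) == [1]

    def test_empty_when_nothing_passes(self):
        geno = _matrix(np.array([[0], [1], [2], [1]]))
        al = AlignedEffects(np.array([0]), np.array([0.1]), np.array([False]),
                            np.array([0.9]), pd.DataFrame())
        assert ld_clump(geno, al, threshold=0.5).size == 0

    def test_index_sets_shrink_with_stricter_parameters(self):
        dos, pos, pvals = _random_instance(99)
        geno = _matrix(dos, positions=pos)
        al = AlignedEffects(np.arange(30), np.zeros(30), np.zeros(30, bool), pvals,
                            pd.DataFrame())
        n_default = ld_clump(geno, al, ClumpParams(r2_threshold=0.1), 0.5).size
        n_tight_r2 = ld_clump(geno, al, ClumpParams(r2_threshold=0.02), 0.5).size
        n_tight_p = ld_clump(geno, al, ClumpParams(r2_threshold=0.1), 1e-3).size
        assert n_tight_r2 <= n_default
        assert n_tight_p <= n_default

    def test_ld_free_data_clumping_equals_thresholding(self):
        rng = np.random.default_rng(7)
        dos = rng.binomial(2, 0.3, size=(1500, 40)).astype(np.int8)
        pvals = 10.0 ** rng.uniform(-6, 0, size=40)
        geno = _matrix(dos, positions=1 + 100 * np.arange(40))  # all in one window
        al = AlignedEffects(np.arange(40), np.zeros(40), np.zeros(40, bool), pvals,
                            pd.DataFrame())
        got = ld_clump(geno, al, ClumpParams(), threshold=0.05)
        assert list(got) == sorted(np.flatnonzero(pvals <= 0.05))


# ---------------------------------------------------------------------------
# scoring and quartiles

class TestScore:
    def test_direct_evaluation(self):
        geno = _matrix(np.array([[0], [1], [2]]))
        al = AlignedEffects(np.array([0]), np.array([np.log(2)]), np.array([False]),
                            np.array([0.01]), pd.DataFrame())
        np.testing.assert_allclose(score(geno, al), [0.0, np.log(2), 2 * np.log(2)], atol=1e-12)

    def test_null_weights_give_zero(self):
        rng = np.random.default_rng(1)
        geno = _matrix(rng.integers(0, 3, (20, 5)).astype(np.int8))
        al = AlignedEffects(np.arange(5), np.zeros(5), np.zeros(5, bool),
                            np.full(5, 0.5), pd.DataFrame())
        assert np.all(score(geno, al) == 0)

    def test_matches_double_loop_oracle_with_missing(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, (50, 20)).astype(np.int8)
        dos[rng.random((50, 20)) < 0.1] = MISSING
        betas = rng.normal(0, 0.3, 20)
        geno = _matrix(dos)
        al = AlignedEffects(np.arange(20), betas, np.zeros(20, bool),
                            np.full(20, 0.5), pd.DataFrame())
        # naive oracle: impute each missing call as 2*freq, then double loop
        freq = np.array([dos[dos[:, j] != MISSING, j].mean() / 2 for j in range(20)])
        want = np.zeros(50)
        for i in range(50):
            for j in range(20):
                gij = dos[i, j] if dos[i, j] != MISSING else 2 * freq[j]
                want[i] += betas[j] * gij
        np.testing.assert_allclose(score(geno, al), want, atol=1e-12)

    def test_linear_in_betas_and_order_invariant(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, (30, 8)).astype(np.int8)
        geno = _matrix(dos)
        b1, b2 = rng.normal(size=8), rng.normal(size=8)
        def sc(b, order=None):
            o = np.arange(8) if order is None else order
            al = AlignedEffects(o, b[o], np.zeros(8, bool), np.full(8, 0.5), pd.DataFrame())
            return score(geno, al)
        np.testing.assert_allclose(sc(b1) + sc(b2), sc(b1 + b2), atol=1e-10)
        perm = rng.permutation(8)
        np.testing.assert_allclose(sc(b1), sc(b1, order=perm), atol=1e-10)


class TestQuartiles:
    def test_uniform_ranks_split_evenly(self):
        cats = quartile_categories(np.arange(1, 101))
        assert [np.sum(cats == q) for q in ("Q1", "Q2", "Q3", "Q4")] == [25, 25, 25, 25]

    def test_constant_scores_raise(self):
        with pytest.raises(DegenerateCategorizationError):
            quartile_categories(np.full(10, 3.0))

    def test_ties_at_median_right_closed(self):
        scores = np.array([1, 2, 3, 4, 5, 6, 6, 6, 7, 8, 9, 10], dtype=float)
        cats = quartile_categories(scores)
        assert len(cats) == 12 and set(cats) <= {"Q1", "Q2", "Q3", "Q4"}
        # right-closed rule re-derived independently
        c25, c50, c75 = np.percentile(scores, [25, 50, 75])
        want = np.array(["Q%d" % (1 + (s > c25) + (s > c50) + (s > c75)) for s in scores])
        assert list(cats) == list(want)
        # each quartile deviates from the even split by at most the tie count
        sizes = [np.sum(cats == q) for q in ("Q1", "Q2", "Q3", "Q4")]
        assert all(abs(s - 3) <= 3 for s in sizes)


# ---------------------------------------------------------------------------
# threshold scan

class TestThresholdScan:
    def test_null_sumstats_give_negligible_delta_auc(self):
        # effects ~ 0: the scanned PRS is pure noise and cannot improve
        # discrimination over the covariate-only model beyond optimism
        from gxekit.covariates import MODEL1_COVARIATES
        covs = {"age_group[40-59]": 0.8, "age_group[60-79]": 1.5, "sex[male]": 0.3,
                "bmi_class[overweight]": 0.7, "bmi_class[obesity1]": 1.1,
                "smoking[former]": 0.5}
        cfg = g.SimulationConfig(n_individuals=5000, n_blocks=25, snps_per_block=2,
                                 within_block_rho=0.0, n_causal=1, causal_beta_sd=0.0,
                                 missing_rate=0.0, extra_pollutants={},
                                 outcome_coefs=g.OutcomeCoefs(intercept=-3.0, prs_effect=0.0,
                                                              slope_effect=0.0, interaction=0.0,
                                                              covariates=covs),
                                 seed=50)
        data = g.simulate_study(cfg)
        rng = np.random.default_rng(0)
        ss = data.sumstats.copy()
        ss["beta"] = rng.normal(0.0, 1e-3, len(ss))
        ss["pvalue"] = rng.uniform(0.0, 1.0, len(ss))
        res = threshold_scan(data.genotypes, ss, data.cohort,
                             covariate_terms=MODEL1_COVARIATES)
        assert abs(res.delta_auc) < 0.01

    def test_informative_sumstats_positive_control(self, small_study):
        cfg = g.SimulationConfig(n_individuals=6000, n_blocks=25, snps_per_block=4,
                                 n_causal=40, causal_beta_sd=0.4, gwas_n_effective=10**6,
                                 missing_rate=0.0, extra_pollutants={},
                                 outcome_coefs=g.OutcomeCoefs(intercept=-2.2, prs_effect=0.6,
                                                              slope_effect=0.0, interaction=0.0),
                                 seed=51)
        data = g.simulate_study(cfg)
        res = threshold_scan(data.genotypes, data.sumstats, data.cohort)
        assert res.delta_auc > 0.02
        prev = data.cohort.groupby(res.quartile)["t2d"].mean()
        assert prev["Q4"] > prev["Q1"]
        assert res.scan["threshold"].is_monotonic_increasing
        assert res.n_variants > 0
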