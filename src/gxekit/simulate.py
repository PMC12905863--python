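"""Synthetic study generator with known ground truth.

Emulates the four inputs of the gene--environment analysis so every
downstream stage is testable without restricted data:

* **Genotypes** -- hard calls in {0,1,2} with block-structured linkage
  disequilibrium.  Each haplotype is a latent AR(1) Gaussian thresholded at
  the variant's allele frequency, so within-block r² is tunable via the
  latent correlation and blocks are independent.  Blocks span < 250 kb and
  consecutive blocks sit > 250 kb apart, matching the clumping window.
* **External GWAS summary statistics** -- reported effect = true effect plus
  Gaussian noise with SE ``1/sqrt(2*maf*(1-maf)*n_effective)`` (the standard
  GWAS approximation); p-values are two-sided Wald, consistent with the
  reported effect and SE.
* **Pollutant panels** -- per participant, concentration(year t) =
  baseline_i + slope_i * t + noise, slopes drawn Normal(slope_mean, slope_sd).
* **Cohort** -- covariates from realistic control marginals; outcome from
  ``P(T2D) = expit(b0 + g_G*z(PRS) + g_E*slope + g_GE*z(PRS)*slope + covars)``
  where the PRS uses the true causal effects.

Every output is a pure function of (config, seed); each stage draws from its
own RNG stream derived from the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .config import SimulationConfig, stage_rng
from .covariates import CATEGORICAL_LEVELS, CONTROL_MARGINALS, dummy_name
from .errors import AlignmentError, ConfigurationError
from .interaction import reri_from_odds_ratios

log = logging.getLogger(__name__)

MISSING = -1  # sentinel in the int8 dosage matrix

_BLOCK_SPACING_BP = 1_000_000   # > 250 kb between consecutive blocks
_SNP_SPACING_BP = 2_000         # keeps any realistic block span < 250 kb


@dataclass
class GenotypeMatrix:
    """Individuals x variants hard-call dosages with variant metadata."""

    dosages: np.ndarray                 # int8 (n, m), MISSING = -1
    variants: pd.DataFrame              # chrom, pos, variant_id, ref, alt, maf
    samples: list[str]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Float copy with missing calls as NaN (alt-allele counts)."""
        g = self.dosages.astype(float)
        g[self.dosages == MISSING] = np.nan
        return g

    def allele_freq(self) -> np.ndarray:
        """Sample alt-allele frequency per variant, ignoring missing calls."""
        g = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to estimate."""

    causal_betas: np.ndarray                       # per-variant true log-OR
    true_outcome_coefs: dict
    true_slopes: pd.DataFrame | None = None        # participant_id x pollutant, true beta1
    true_prs: np.ndarray | None = None             # raw true-score per individual
    achieved_prevalence: float | None = None
    implied_true_reri: float | None = None         # high-G x adverse-E binary contrast
    maf: np.ndarray | None = None


@dataclass
class SimDataset:
    """One fully generated synthetic study."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    sumstats: pd.DataFrame
    exposures: pd.DataFrame
    cohort: pd.DataFrame
    truth: GroundTruth = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# genotypes

def _draw_haplotype(rng: np.random.Generator, n: int, thresh: np.ndarray, rho: float) -> np.ndarray:
    """Latent AR(1) Gaussian haplotypes thresholded to per-variant frequencies."""
    m = thresh.size
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        e = rng.standard_normal((n, m - 1))
        a = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + a * e[:, j - 1]
    return (z < thresh).astype(np.int8)


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


def generate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Block-LD hard-call genotypes; alt allele is the counted (frequency ``maf``) allele."""
    rng = stage_rng(config.seed, "genotypes")
    n, m = config.n_individuals, config.n_variants
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    if config.maf_range[0] == config.maf_range[1]:
        maf = np.full(m, config.maf_range[0])

    # optional shifted subpopulation (ancestry outliers for PC-based QC)
    sub = np.zeros(n, dtype=bool)
    if config.subpop_fraction > 0:
        k = int(round(config.subpop_fraction * n))
        sub[rng.choice(n, size=k, replace=False)] = True

    dos = np.empty((n, m), dtype=np.int8)
    for b in range(config.n_blocks):
        j0, j1 = b * config.snps_per_block, (b + 1) * config.snps_per_block
        thr = norm.ppf(np.clip(maf[j0:j1], 1e-12, 1 - 1e-12))
        h1 = _draw_haplotype(rng, n, thr, config.within_block_rho)
        h2 = _draw_haplotype(rng, n, thr, config.within_block_rho)
        dos[:, j0:j1] = h1 + h2
        if sub.any() and config.subpop_shift != 0.0:
            maf_s = expit(logit(np.clip(maf[j0:j1], 1e-6, 1 - 1e-6)) + config.subpop_shift)
            thr_s = norm.ppf(maf_s)
            ns = int(sub.sum())
            g1 = _draw_haplotype(rng, ns, thr_s, config.within_block_rho)
            g2 = _draw_haplotype(rng, ns, thr_s, config.within_block_rho)
            dos[sub, j0:j1] = g1 + g2

    if config.missing_rate > 0:
        dos[rng.random((n, m)) < config.missing_rate] = MISSING

    block = np.repeat(np.arange(config.n_blocks), config.snps_per_block)
    within = np.tile(np.arange(config.snps_per_block), config.n_blocks)
    pos = 1 + block * _BLOCK_SPACING_BP + within * _SNP_SPACING_BP
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = pd.DataFrame({
        "chrom": "1",
        "pos": pos.astype(np.int64),
        "variant_id": [f"rs{b}_{w}" for b, w in zip(block, within)],
        "ref": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "alt": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "maf": maf,
        "block": block,
    })
    samples = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dos, variants, samples)


def make_ground_truth(genotypes: GenotypeMatrix, config: SimulationConfig) -> GroundTruth:
    """Draw causal variants/effects; deterministic given (config, seed)."""
    rng = stage_rng(config.seed, "truth")
    m = genotypes.n_variants
    betas = np.zeros(m)
    causal = rng.choice(m, size=config.n_causal, replace=False)
    betas[causal] = rng.normal(0.0, config.causal_beta_sd, size=config.n_causal)
    oc = config.outcome_coefs
    return GroundTruth(
        causal_betas=betas,
        true_outcome_coefs={
            "intercept": oc.intercept, "prs_effect": oc.prs_effect,
            "slope_effect": oc.slope_effect, "interaction": oc.interaction,
            "covariates": dict(oc.covariates),
        },
        maf=genotypes.variants["maf"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# summary statistics

def generate_sumstats(genotypes: GenotypeMatrix, truth: GroundTruth,
                      config: SimulationConfig) -> pd.DataFrame:
    """Noisy external summary statistics aligned to the genotype variants."""
    if truth.causal_betas.shape[0] != genotypes.n_variants:
        raise AlignmentError("truth.causal_betas not aligned to genotype variants")
    rng = stage_rng(config.seed, "sumstats")
    maf = genotypes.variants["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.gwas_n_effective)
    beta_hat = truth.causal_betas + rng.normal(0.0, 1.0, size=se.size) * se
    z = beta_hat / se
    pval = 2.0 * norm.sf(np.abs(z))
    v = genotypes.variants
    return pd.DataFrame({
        "chrom": v["chrom"], "pos": v["pos"], "variant_id": v["variant_id"],
        "effect_allele": v["alt"], "other_allele": v["ref"],
        "beta": beta_hat, "se": se, "pvalue": pval,
    })


# ---------------------------------------------------------------------------
# exposures

def generate_exposures(config: SimulationConfig,
                       panel: bool = True) -> tuple[pd.DataFrame | None, pd.DataFrame]:
    """Long-format annual pollutant panel plus the true per-participant slopes.

    Returns ``(panel, true_slopes)``; panel columns are participant_id,
    pollutant, year, concentration; true_slopes is participant_id x pollutant.
    With ``panel=False`` the (identically drawn) long table is not
    materialised -- useful in replicated simulations that only need slopes.
    """
    if len(config.years) < 2:
        raise ConfigurationError("need >= 2 exposure years")
    rng = stage_rng(config.seed, "exposures")
    n = config.n_individuals
    pids = [f"S{i:06d}" for i in range(n)]
    years = np.asarray(sorted(config.years))
    t = np.arange(years.size, dtype=float)

    frames, slope_cols = [], {}
    for pol, pp in config.pollutant_params().items():
        baseline = rng.normal(pp.baseline_mean, pp.baseline_sd, size=n)
        slope = rng.normal(pp.slope_mean, pp.slope_sd, size=n)
        noise = rng.normal(0.0, pp.noise_sd, size=(n, years.size)) if pp.noise_sd > 0 else 0.0
        if panel:
            conc = baseline[:, None] + slope[:, None] * t[None, :] + noise
            frames.append(pd.DataFrame({
                "participant_id": np.repeat(pids, years.size),
                "pollutant": pol,
                "year": np.tile(years, n),
                "concentration": conc.ravel(),
            }))
        slope_cols[pol] = slope
    long = pd.concat(frames, ignore_index=True) if panel else None
    true_slopes = pd.DataFrame({"participant_id": pids, **slope_cols})
    return long, true_slopes


# ---------------------------------------------------------------------------
# cohort

def _score_true_prs(genotypes: GenotypeMatrix, truth: GroundTruth) -> np.ndarray:
    g = genotypes.dosage_float()
    freq = genotypes.allele_freq()
    fill = np.where(np.isfinite(freq), 2.0 * freq, 0.0)
    idx = np.where(np.isnan(g))
    g[idx] = fill[idx[1]]
    return g @ truth.causal_betas


def generate_cohort(genotypes: GenotypeMatrix, truth: GroundTruth,
                    exposures_true_slopes: pd.DataFrame,
                    config: SimulationConfig) -> pd.DataFrame:
    """Covariates + outcome for every genotyped participant.

    Side effects on ``truth``: fills true_prs, true_slopes, achieved
    prevalence and the implied true RERI for the (top-quartile true PRS) x
    (positive slope) contrast, computed from the noiseless risks.
    """
    rng = stage_rng(config.seed, "cohort")
    pids = list(genotypes.samples)
    if list(exposures_true_slopes["participant_id"]) != pids:
        raise AlignmentError("exposure participants do not match genotype samples")
    n = len(pids)

    cohort = pd.DataFrame({"participant_id": pids})
    for var, levels in CATEGORICAL_LEVELS.items():
        probs = np.asarray(CONTROL_MARGINALS[var], dtype=float)
        draw = rng.choice(len(levels), size=n, p=probs / probs.sum())
        cohort[var] = np.asarray(levels, dtype=object)[draw]

    prs_raw = _score_true_prs(genotypes, truth)
    sd = prs_raw.std()
    z = (prs_raw - prs_raw.mean()) / sd if sd > 0 else np.zeros(n)
    slope = exposures_true_slopes[config.primary_pollutant].to_numpy()

    oc = truth.true_outcome_coefs
    lp = (oc["intercept"] + oc["prs_effect"] * z + oc["slope_effect"] * slope
          + oc["interaction"] * z * slope)
    for colname, beta in oc["covariates"].items():
        var, lev = colname.split("[")
        lp = lp + beta * (cohort[var] == lev.rstrip("]")).to_numpy(dtype=float)
    p = expit(lp)
    cohort["t2d"] = (rng.random(n) < p).astype(int)

    truth.true_prs = prs_raw
    truth.true_slopes = exposures_true_slopes
    truth.achieved_prevalence = float(cohort["t2d"].mean())
    truth.implied_true_reri = implied_true_reri_from_risks(z, slope, p)
    log.info("synthetic cohort: n=%d, prevalence=%.4f", n, truth.achieved_prevalence)
    return cohort


def implied_true_reri_from_risks(z_prs: np.ndarray, slope: np.ndarray,
                                 risk: np.ndarray) -> float:
    """Population RERI implied by the true model for the binary contrast
    high genetic risk (top-quartile true PRS) x adverse exposure (slope > 0).

    Cell odds are formed from the mean true risk within each cell; odds
    ratios are taken against the (low-G, improving-E) cell and combined with
    the standard additive-interaction formula.  NaN if any cell is empty.
    """
    high_g = z_prs >= np.percentile(z_prs, 75)
    adv_e = slope > 0
    odds = {}
    for gg in (0, 1):
        for ee in (0, 1):
            cell = (high_g == bool(gg)) & (adv_e == bool(ee))
            if not cell.any():
                return float("nan")
            r = risk[cell].mean()
            odds[(gg, ee)] = r / (1.0 - r)
    or10 = odds[(1, 0)] / odds[(0, 0)]
    or01 = odds[(0, 1)] / odds[(0, 0)]
    or11 = odds[(1, 1)] / odds[(0, 0)]
    return reri_from_odds_ratios(or10, or01, or11)


# ---------------------------------------------------------------------------
# orchestration

def simulate_study(config: SimulationConfig) -> SimDataset:
    """Run all four generator stages and bundle the result."""
    genotypes = generate_genotypes(config)
    truth = make_ground_truth(genotypes, config)
    sumstats = generate_sumstats(genotypes, truth, config)
    panel, true_slopes = generate_exposures(config)
    cohort = generate_cohort(genotypes, truth, true_slopes, config)
    return SimDataset(config, genotypes, sumstats, panel, cohort, truth)
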