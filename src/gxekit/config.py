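"""Configuration dataclasses for simulation, QC, clumping and pipeline runs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: default p-value threshold grid for the clumping-and-thresholding scan;
#: endpoints 5e-8 and 0.5, interior points on a standard log-spaced ladder
DEFAULT_P_GRID: tuple[float, ...] = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.3, 0.5)

_STAGE_IDS = {"truth": 0, "genotypes": 1, "sumstats": 2, "exposures": 3, "cohort": 4, "bootstrap": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One independent RNG stream per generator stage, derived from the master seed.

    Regenerating one stage (e.g. exposures) with an unchanged seed yields
    identical output regardless of whether other stages were re-run.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_IDS[stage],)))


@dataclass(frozen=True)
class PollutantParams:
    """Trend-model parameters for one pollutant (all in the pollutant's unit)."""

    slope_mean: float
    slope_sd: float
    baseline_mean: float
    baseline_sd: float
    noise_sd: float = 1.0


# Taiwan-like defaults for the three secondary pollutants (unit: µg/m³ except
# O3/NO2/SO2 reported in their customary units, treated numerically alike).
DEFAULT_EXTRA_POLLUTANTS: dict[str, PollutantParams] = {
    "no2": PollutantParams(-0.44, 0.59, 14.3, 6.39, 0.5),
    "so2": PollutantParams(-0.13, 0.13, 3.34, 0.95, 0.1),
    "o3": PollutantParams(-0.01, 0.61, 45.4, 4.33, 0.5),
}


@dataclass
class OutcomeCoefs:
    """True coefficients of the logistic outcome model.

    ``prs_effect`` multiplies the z-scored true polygenic score,
    ``slope_effect`` the primary-pollutant slope (per 1 unit/year), and
    ``interaction`` their product.  ``covariates`` maps design-matrix column
    names (see :mod:`gxekit.covariates`) to log-odds effects; empty by default
    so the crude and adjusted models target the same estimand.

    Defaults give, under the default exposure distribution (slope mean -1.56),
    a marginal top-vs-bottom PRS-quartile odds ratio near 1.4 and a slope
    odds ratio near 1.036 per unit/year -- the strength of association the
    emulated study reports.  Note the genetic effect at the mean slope is
    ``prs_effect + interaction * slope_mean``, so the main effect is set
    above the target contrast to offset the negative mean trend.
    """

    intercept: float = -2.95
    prs_effect: float = 0.2
    slope_effect: float = 0.035
    interaction: float = 0.05
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic study.

    Scalar trend fields (slope_mean .. noise_sd) parameterise the primary
    pollutant (``primary_pollutant``); further pollutants are generated from
    ``extra_pollutants``.
    """

    n_individuals: int = 2000
    n_blocks: int = 25
    snps_per_block: int = 8
    within_block_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 40
    causal_beta_sd: float = 0.08
    gwas_n_effective: int = 200_000
    years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)
    slope_mean: float = -1.56
    slope_sd: float = 0.88
    baseline_mean: float = 26.7
    baseline_sd: float = 7.64
    noise_sd: float = 1.0
    primary_pollutant: str = "pm25"
    extra_pollutants: dict[str, PollutantParams] = field(
        default_factory=lambda: dict(DEFAULT_EXTRA_POLLUTANTS)
    )
    outcome_coefs: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    missing_rate: float = 0.01
    subpop_fraction: float = 0.0    # small shifted subpopulation for PC-outlier tests
    subpop_shift: float = 0.0       # allele-frequency logit shift of that subpopulation
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_blocks, self.snps_per_block) <= 0:
            raise ConfigurationError("n_individuals, n_blocks and snps_per_block must be positive")
        low, high = self.maf_range
        if not (0 <= low < high <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 <= low < high <= 0.5, got {self.maf_range}")
        if not (0 <= self.within_block_rho < 1):
            raise ConfigurationError("within_block_rho must be in [0, 1)")
        if self.n_causal > self.n_blocks * self.snps_per_block:
            raise ConfigurationError("n_causal exceeds the total number of variants")
        if not (0 <= self.missing_rate <= 1):
            raise ConfigurationError("missing_rate must be a probability")
        if len(self.years) < 2:
            raise ConfigurationError("at least 2 exposure years are required")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.snps_per_block

    def pollutant_params(self) -> dict[str, PollutantParams]:
        """All pollutants, primary first."""
        out = {
            self.primary_pollutant: PollutantParams(
                self.slope_mean, self.slope_sd, self.baseline_mean, self.baseline_sd, self.noise_sd
            )
        }
        out.update(self.extra_pollutants)
        return out


@dataclass
class QCParams:
    """Variant- and individual-level quality-control thresholds."""

    max_missing_rate: float = 0.02      # per individual and per variant
    min_maf: float = 0.05
    hwe_p_cases: float = 1e-10
    hwe_p_controls: float = 1e-6
    het_sd: float = 3.0                 # heterozygosity outlier band, in SDs
    max_pihat: float = 0.2              # relatedness cutoff
    min_ibd_markers: int = 1000         # skip relatedness below this marker count
    pc_outlier_sd: float = 6.0          # PC1/PC2 ancestry-outlier band, in SDs

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "max_pihat"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("hwe_p_cases", "hwe_p_controls"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        if self.het_sd <= 0 or self.pc_outlier_sd <= 0:
            raise ConfigurationError("het_sd and pc_outlier_sd must be positive")


@dataclass
class ClumpParams:
    """Clumping-and-thresholding parameters (r² window and p-value grid)."""

    r2_threshold: float = 0.1
    window_kb: float = 250.0
    p_thresholds: tuple[float, ...] = DEFAULT_P_GRID

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ConfigurationError("r2_threshold must be in (0, 1)")
        if self.window_kb <= 0:
            raise ConfigurationError("window_kb must be positive")
        ts = tuple(self.p_thresholds)
        if not ts or any(not (0 < t <= 1) for t in ts):
            raise ConfigurationError("p_thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ConfigurationError("p_thresholds must be strictly increasing")
        self.p_thresholds = ts


def config_to_dict(cfg) -> dict:
    """Recursively convert a config dataclass to plain JSON-able types."""
    def conv(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (tuple, list)):
            return [conv(v) for v in x]
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x
    return conv(cfg)
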