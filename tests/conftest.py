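import numpy as np
import pandas as pd
import pytest

import gxekit as g
from gxekit.prs import quartile_categories


@pytest.fixture(scope="session")
def small_study():
    """One fully generated small synthetic study shared across tests."""
    cfg = g.SimulationConfig(n_individuals=600, n_blocks=20, snps_per_block=6,
                             n_causal=24, causal_beta_sd=0.15, missing_rate=0.01, seed=11)
    return g.simulate_study(cfg)


def quick_cohort(n: int, seed: int, *, interaction=0.0, slope_effect=np.log(1.05),
                 prs_effect=0.15, intercept=-2.9, slope_mean=-1.56, slope_sd=0.88):
    """Minimal analysis-ready cohort (true PRS quartiles + true slopes).

    Used by replicated simulations that test model calibration rather than
    the genotype pipeline itself.
    """
    cfg = g.SimulationConfig(
        n_individuals=n, n_blocks=4, snps_per_block=2, n_causal=8,
        causal_beta_sd=0.3, missing_rate=0.0, extra_pollutants={},
        slope_mean=slope_mean, slope_sd=slope_sd,
        outcome_coefs=g.OutcomeCoefs(intercept=intercept, prs_effect=prs_effect,
                                     slope_effect=slope_effect, interaction=interaction),
        seed=seed)
    geno = g.generate_genotypes(cfg)
    truth = g.make_ground_truth(geno, cfg)
    _, slopes = g.generate_exposures(cfg, panel=False)
    cohort = g.generate_cohort(geno, truth, slopes, cfg)
    cohort = cohort[["participant_id", "t2d"]].copy()
    cohort["pm25_slope"] = slopes["pm25"].to_numpy()
    cohort["prs_quartile"] = quartile_categories(truth.true_prs)
    return cohort, truth
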