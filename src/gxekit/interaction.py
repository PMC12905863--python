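"""Additive and multiplicative gene--environment interaction.

Additive interaction between the polygenic-risk category and the pollutant
trend is quantified by the relative excess risk due to interaction,

    RERI = exp(b1 + b2 + b3) - exp(b1) - exp(b2) + 1        (standard form)

where b1, b2, b3 are the logistic coefficients of the pollutant slope, the
PRS category, and their product.  A second variant omitting the -exp(b1)
term is selectable as ``"as_printed"`` (it circulates in some applied work,
plausibly a typesetting loss); outputs always carry the variant label.
Confidence intervals come from a percentile bootstrap over individuals.
Multiplicative interaction is the Wald test of each cross-product term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .covariates import ADJUSTMENT_SETS
from .design import build_design
from .errors import ConfigurationError, ConvergenceError
from .logistic import LogisticFit, drop_quasi_separated, irls_logit, wald_test  # noqa: F401

log = logging.getLogger(__name__)

QUARTILES = ("Q1", "Q2", "Q3", "Q4")
FORMULA_VARIANTS = ("standard", "as_printed")


def reri_from_coefs(beta1: float, beta2: float, beta3: float,
                    variant: str = "standard") -> float:
    """RERI from the slope (b1), PRS-category (b2) and product (b3) coefficients."""
    for b in (beta1, beta2, beta3):
        if not np.isfinite(b):
            raise ConfigurationError("RERI requires finite coefficients")
    if variant == "standard":
        return float(np.exp(beta1 + beta2 + beta3) - np.exp(beta1) - np.exp(beta2) + 1.0)
    if variant == "as_printed":
        return float(np.exp(beta1 + beta2 + beta3) - np.exp(beta2) + 1.0)
    raise ConfigurationError(f"unknown RERI variant {variant!r}")


def reri_from_odds_ratios(or10: float, or01: float, or11: float) -> float:
    """Standard RERI as OR11 - OR10 - OR01 + 1 (joint/marginal odds ratios)."""
    return float(or11 - or10 - or01 + 1.0)


@dataclass
class InteractionResult:
    """Joint or stratified slope-by-PRS interaction analysis."""

    mode: str                           # "joint" | "stratified"
    slope_col: str
    adjustment: str
    per_quartile: pd.DataFrame          # prs_category, or, ci_low, ci_high, p
    products: pd.DataFrame | None       # term, coef, z, p (joint mode only)
    fit: LogisticFit | None             # the joint fit (joint mode only)


def interaction_fit(cohort: pd.DataFrame, slope_col: str,
                    adjustment: str = "model1", mode: str = "joint") -> InteractionResult:
    """Slope-by-PRS-quartile interaction model.

    joint mode: one model with the slope main effect, three quartile
    indicators, three cross-products and the adjustment covariates; the
    per-quartile slope OR is exp(b1 + b3(q)) (exp(b1) in Q1).  stratified
    mode: the slope model fitted separately within each quartile.
    """
    if "prs_quartile" not in cohort.columns:
        raise ConfigurationError("cohort needs a prs_quartile column")
    covars = ADJUSTMENT_SETS[adjustment] if adjustment in ADJUSTMENT_SETS else None
    if covars is None:
        raise ConfigurationError(f"unknown adjustment set {adjustment!r}")

    if mode == "joint":
        terms = [slope_col, "prs_quartile", f"{slope_col}:prs_quartile"] + covars
        fit = _fit(cohort, terms)
        rows, prods = [], []
        for q in QUARTILES:
            w = {slope_col: 1.0}
            if q != "Q1":
                w[f"{slope_col}:prs_quartile[{q}]"] = 1.0
            if not all(fit.has_term(t) for t in w):
                rows.append({"prs_category": q, "or": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan})
                continue
            est, se = fit.linear_combo(w)
            z = est / se
            rows.append({"prs_category": q, "or": float(np.exp(est)),
                         "ci_low": float(np.exp(est - 1.959963984540054 * se)),
                         "ci_high": float(np.exp(est + 1.959963984540054 * se)),
                         "p": float(2 * norm.sf(abs(z)))})
        for q in QUARTILES[1:]:
            term = f"{slope_col}:prs_quartile[{q}]"
            if not fit.has_term(term):
                continue
            z, p = fit.wald(term)
            prods.append({"term": term, "coef": fit.coef(term), "z": z, "p": p})
        return InteractionResult("joint", slope_col, adjustment,
                                 pd.DataFrame(rows), pd.DataFrame(prods), fit)

    if mode == "stratified":
        rows = []
        for q in QUARTILES:
            stratum = cohort[cohort["prs_quartile"] == q]
            if stratum.empty:
                log.warning("empty PRS stratum %s skipped", q)
                continue
            sfit = _fit(stratum, [slope_col] + covars)
            or_, lo, hi = sfit.odds_ratio(slope_col)
            _, p = sfit.wald(slope_col)
            rows.append({"prs_category": q, "or": or_, "ci_low": lo, "ci_high": hi, "p": p})
        return InteractionResult("stratified", slope_col, adjustment,
                                 pd.DataFrame(rows), None, None)

    raise ConfigurationError(f"unknown mode {mode!r}")


def _fit(cohort: pd.DataFrame, terms: list[str]) -> LogisticFit:
    X, names = build_design(cohort, terms)
    y = cohort["t2d"].to_numpy(dtype=float)
    keep = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]
    X, names, sep = drop_quasi_separated(X, names, y)
    if sep:
        log.warning("dropped quasi-separated indicator column(s): %s", ", ".join(sep))
    return irls_logit(X, y, terms=names)


# ---------------------------------------------------------------------------
# bootstrap RERI

@dataclass
class RERIResult:
    prs_category: str                   # "Q2"/"Q3"/"Q4" or "high_vs_rest"
    slope_col: str
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_failed_refits: int
    formula_variant: str
    unreliable: bool                    # > 5% failed refits


def _reri_terms(cohort: pd.DataFrame, slope_col: str, contrast: str,
                covars: list[str]) -> tuple[pd.DataFrame, list[str], list[tuple[str, str, str, str]]]:
    """Working cohort, model terms and (label, b1, b2, b3) contrast triples."""
    work = cohort.copy()
    if contrast == "quartiles":
        terms = [slope_col, "prs_quartile", f"{slope_col}:prs_quartile"] + covars
        triples = [(q, slope_col, f"prs_quartile[{q}]", f"{slope_col}:prs_quartile[{q}]")
                   for q in QUARTILES[1:]]
    elif contrast == "binary":
        # ground-truth comparable contrast: top-quartile PRS x worsening trend
        work["high_prs"] = (work["prs_quartile"] == "Q4").astype(float)
        work["adverse_trend"] = (work[slope_col] > 0).astype(float)
        terms = ["adverse_trend", "high_prs", "adverse_trend:high_prs"] + covars
        triples = [("high_vs_rest", "adverse_trend", "high_prs", "adverse_trend:high_prs")]
    else:
        raise ConfigurationError(f"unknown contrast {contrast!r}")
    return work, terms, triples


def reri_bootstrap(cohort: pd.DataFrame, slope_col: str, adjustment: str = "model1",
                   n_boot: int = 1000, seed: int = 0,
                   formula_variant: str = "standard",
                   contrast: str = "quartiles") -> list[RERIResult]:
    """Percentile-bootstrap confidence intervals for the RERI.

    Individuals are resampled with replacement (same n, unstratified), the
    interaction model refitted, and the RERI recomputed per PRS contrast;
    the CI is the 2.5/97.5 percentile over successful refits and the point
    estimate comes from the original fit.  Non-converged refits are dropped
    and counted; results with > 5% failures are flagged unreliable, and all
    refits failing is a hard error.
    """
    if formula_variant not in FORMULA_VARIANTS:
        raise ConfigurationError(f"unknown RERI formula variant {formula_variant!r}")
    covars = ADJUSTMENT_SETS[adjustment]
    work, terms, triples = _reri_terms(cohort, slope_col, contrast, covars)

    X, names = build_design(work, terms)
    y = work["t2d"].to_numpy(dtype=float)
    keep = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]
    X, names, sep = drop_quasi_separated(X, names, y)
    if sep:
        log.warning("dropped quasi-separated indicator column(s): %s", ", ".join(sep))
    base = irls_logit(X, y, terms=names)
    if not base.converged:
        raise ConvergenceError("base interaction model did not converge")
    estimable = [t for t in triples if all(base.has_term(x) for x in t[1:])]
    for t in triples:
        if t not in estimable:
            log.warning("RERI contrast %s not estimable (separated level); skipped", t[0])
    triples = estimable

    def reri_of(fit: LogisticFit) -> dict[str, float]:
        out = {}
        for lab, b1, b2, b3 in triples:
            if not all(fit.has_term(t) for t in (b1, b2, b3)):
                raise KeyError(lab)   # caught in the bootstrap loop -> failed refit
            out[lab] = reri_from_coefs(fit.coef(b1), fit.coef(b2), fit.coef(b3), formula_variant)
        return out

    point = reri_of(base)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    n = y.size
    draws: dict[str, list[float]] = {lab: [] for lab, *_ in triples}
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        Xb, nb, _ = drop_quasi_separated(Xb, names, yb)
        try:
            fit = irls_logit(Xb, yb, terms=nb, check_rank=False)
            if not fit.converged:
                raise ConvergenceError
            vals = reri_of(fit)
        except (ConvergenceError, KeyError, np.linalg.LinAlgError):
            failed += 1
            continue
        for lab, val in vals.items():
            draws[lab].append(val)

    if failed == n_boot:
        raise ConvergenceError("all bootstrap refits failed")
    if failed > 0.05 * n_boot:
        log.warning("%d/%d bootstrap refits failed; RERI CIs flagged unreliable", failed, n_boot)

    out = []
    for lab, *_ in triples:
        vals = np.asarray(draws[lab])
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out.append(RERIResult(lab, slope_col, point[lab], float(lo), float(hi),
                              n_boot, failed, formula_variant, failed > 0.05 * n_boot))
    return out
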