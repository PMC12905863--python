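"""Contingency-table statistics and crude/adjusted logistic odds-ratio models.

Reproduces the arithmetic of a case/non-case descriptive table (2x2
cross-product odds ratios with Wald confidence intervals, Pearson chi-square
tests) and the single-/multi-pollutant logistic model suites.  Continuous
slope terms enter per 1 unit/year without standardisation; complete-case
analysis is used when covariates are missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm

from .covariates import ADJUSTMENT_SETS
from .design import build_design
from .errors import (
    ConfigurationError,
    DegenerateTableError,
    UndefinedORError,
)
from .logistic import LogisticFit, drop_quasi_separated, irls_logit

log = logging.getLogger(__name__)

_Z95 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class OddsRatio:
    or_: float
    ci_low: float
    ci_high: float


def two_by_two_or(a: float, b: float, c: float, d: float,
                  continuity: bool = False) -> OddsRatio:
    """Cross-product odds ratio of a 2x2 table with its 95% Wald CI.

    Cells are a = exposed cases, b = unexposed cases, c = exposed non-cases,
    d = unexposed non-cases, so OR = (a*d)/(b*c).  A zero cell makes the OR
    or its CI undefined; with ``continuity`` the Haldane--Anscombe 0.5
    correction is added to every cell instead.
    """
    if min(a, b, c, d) < 0:
        raise ConfigurationError("2x2 cells must be non-negative")
    if min(a, b, c, d) == 0:
        if not continuity:
            raise UndefinedORError("zero cell in 2x2 table; enable continuity correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatio(float(or_), float(or_ * np.exp(-_Z95 * se)), float(or_ * np.exp(_Z95 * se)))


def chisq_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an RxC count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError("need at least a 2x2 table")
    if (t < 0).any():
        raise ConfigurationError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row/column margin")
    stat, p, df, _ = chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def fit_logistic(cohort: pd.DataFrame, terms: list[str],
                 outcome: str = "t2d", **irls_kwargs) -> LogisticFit:
    """Fit ``outcome ~ intercept + terms`` by IRLS on complete cases."""
    if outcome not in cohort.columns:
        raise ConfigurationError(f"cohort is missing outcome column {outcome!r}")
    X, names = build_design(cohort, terms)
    y = pd.to_numeric(cohort[outcome], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("complete-case analysis: dropped %d of %d rows", dropped, len(keep))
    X, y = X[keep], y[keep]
    X, names, sep = drop_quasi_separated(X, names, y)
    if sep:
        log.warning("dropped quasi-separated indicator column(s): %s", ", ".join(sep))
    return irls_logit(X, y, terms=names, **irls_kwargs)


def model_suite(cohort: pd.DataFrame, exposure_terms: list[str],
                adjustments: list[str] | None = None,
                multi_pollutant: bool = False) -> pd.DataFrame:
    """Odds-ratio table for exposure terms under each adjustment set.

    ``adjustments`` are names in {"crude", "model1", "model2"}.  In single-
    pollutant mode each exposure term is modelled separately; in
    multi-pollutant mode all exposure terms enter one joint model.
    """
    adjustments = adjustments or ["crude", "model1", "model2"]
    for adj in adjustments:
        if adj not in ADJUSTMENT_SETS:
            raise ConfigurationError(f"unknown adjustment set {adj!r}")
    groups = [list(exposure_terms)] if multi_pollutant else [[t] for t in exposure_terms]

    rows = []
    for adj in adjustments:
        covars = ADJUSTMENT_SETS[adj]
        for grp in groups:
            fit = fit_logistic(cohort, grp + covars)
            for term in grp:
                cols = _term_columns(fit, term)
                if not cols:
                    log.warning("term %r dropped from %s model (separated levels); no OR reported",
                                term, adj)
                for name in cols:
                    or_, lo, hi = fit.odds_ratio(name)
                    _, p = fit.wald(name)
                    rows.append({"model": adj, "term": term, "level": name,
                                 "or": or_, "ci_low": lo, "ci_high": hi, "p": p,
                                 "n_obs": fit.n_obs, "converged": fit.converged})
    return pd.DataFrame(rows)


def _term_columns(fit: LogisticFit, term: str) -> list[str]:
    """Design columns belonging to one requested term (dummies share the prefix)."""
    if term in fit.terms:
        return [term]
    prefix = f"{term}["
    return [t for t in fit.terms if t.startswith(prefix)]
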