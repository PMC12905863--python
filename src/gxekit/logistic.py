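"""Maximum-likelihood logistic regression by iteratively reweighted least squares.

This is the numerical core shared by the association, PRS-scan and interaction
stages.  Newton--Raphson (equivalently IRLS) with step-halving; convergence is
declared when the largest absolute coefficient update falls below ``tol``
(default 1e-8) within ``max_iter`` (default 50) iterations.  The reported
covariance is the inverse observed information X'WX evaluated at the final
coefficients, so Wald odds ratios and confidence intervals follow directly.

Perfect separation (including a constant outcome) manifests as diverging
coefficients and vanishing curvature; such fits are flagged unusable
(``converged=False``) rather than raising, so that bootstrap loops can count
and drop them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import DegenerateTestError, RankDeficiencyError

_Z95 = norm.ppf(0.975)


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, covariance and diagnostics."""

    terms: list[str]
    params: np.ndarray
    cov: np.ndarray
    n_obs: int
    converged: bool
    n_iter: int
    loglike: float
    loglike_null: float
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.terms)}

    def has_term(self, term: str) -> bool:
        return term in self._index

    def coef(self, term: str) -> float:
        return float(self.params[self._index[term]])

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov[self._index[term], self._index[term]]))

    def odds_ratio(self, term: str, alpha: float = 0.05) -> tuple[float, float, float]:
        """(OR, ci_low, ci_high) for one term, Wald interval."""
        z = norm.ppf(1 - alpha / 2)
        b, s = self.coef(term), self.se(term)
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s))

    def wald(self, term: str) -> tuple[float, float]:
        """Wald z statistic and two-sided p for one coefficient."""
        var = self.cov[self._index[term], self._index[term]]
        if not np.isfinite(var) or var <= 0:
            raise DegenerateTestError(f"zero/invalid variance for term {term!r}")
        z = self.coef(term) / float(np.sqrt(var))
        return float(z), float(2 * norm.sf(abs(z)))

    def linear_combo(self, weights: dict[str, float]) -> tuple[float, float]:
        """Estimate and SE of a linear combination of coefficients."""
        w = np.zeros(len(self.terms))
        for t, c in weights.items():
            w[self._index[t]] = c
        est = float(w @ self.params)
        se = float(np.sqrt(w @ self.cov @ w))
        return est, se

    def nagelkerke_r2(self) -> float:
        n = self.n_obs
        cs = 1.0 - np.exp(2.0 * (self.loglike_null - self.loglike) / n)
        max_cs = 1.0 - np.exp(2.0 * self.loglike_null / n)
        return float(cs / max_cs) if max_cs > 0 else 0.0


def _loglike(y: np.ndarray, eta: np.ndarray) -> float:
    # stable binomial log-likelihood: y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _null_loglike(y: np.ndarray) -> float:
    p = y.mean()
    if p <= 0 or p >= 1:
        return 0.0
    n = y.size
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def irls_logit(
    X: np.ndarray,
    y: np.ndarray,
    terms: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    check_rank: bool = True,
) -> LogisticFit:
    """Fit ``P(y=1) = expit(X beta)`` by Newton--Raphson/IRLS.

    Parameters
    ----------
    X : (n, p) design matrix including any intercept column.
    y : (n,) binary outcome in {0, 1}.
    terms : column names; defaults to ``x0..x{p-1}``.
    check_rank : verify full column rank first and raise
        :class:`RankDeficiencyError` otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if terms is None:
        terms = [f"x{i}" for i in range(p)]
    if check_rank and np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError(f"design matrix has rank < {p} (collinear terms)")

    beta = np.zeros(p)
    # warm start for a leading all-ones intercept column
    ybar = y.mean()
    if 0 < ybar < 1 and np.all(X[:, 0] == 1.0):
        beta[0] = np.log(ybar / (1 - ybar))

    ll = _loglike(y, X @ beta)
    converged = False
    it = 0
    singular = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        XtWX = (X * w[:, None]).T @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        for _ in range(25):
            cand = beta + scale * step
            ll_new = _loglike(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = _loglike(y, X @ beta)
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    XtWX = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        singular = True
    # separation heuristics: diverging coefficients or vanished curvature
    if converged and (np.max(np.abs(beta)) > 30 or not np.all(np.isfinite(cov))):
        converged = False
    if singular or ybar in (0.0, 1.0):
        converged = False

    return LogisticFit(
        terms=list(terms), params=beta, cov=cov, n_obs=n,
        converged=converged, n_iter=it, loglike=ll, loglike_null=_null_loglike(y),
    )


def drop_quasi_separated(
    X: np.ndarray, names: list[str], y: np.ndarray,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove indicator columns whose carriers are all cases or all non-cases.

    Such dummies (typically rare covariate levels) have an infinite MLE and
    stall Newton iterations; dropping one merges the level into the
    reference, the conventional remedy.  Returns (X, names, dropped_names).
    """
    dropped: list[str] = []
    names = list(names)
    changed = True
    while changed:
        changed = False
        keep = []
        for j, nm in enumerate(names):
            col = X[:, j]
            support = col != 0.0
            if nm != "intercept" and support.any() and not support.all():
                s = y[support].sum()
                if s == 0 or s == support.sum():
                    dropped.append(nm)
                    changed = True
                    continue
            keep.append(j)
        X, names = X[:, keep], [names[j] for j in keep]
        # implicit reference groups: for a pure categorical dummy block, rows
        # with all dummies 0 form the reference; if that group is all-case or
        # case-free every contrast against it is infinite -> drop the block
        groups: dict[str, list[int]] = {}
        for j, nm in enumerate(names):
            if "[" in nm and ":" not in nm:
                groups.setdefault(nm.split("[", 1)[0], []).append(j)
        for var, js in groups.items():
            block = X[:, js]
            if not np.isin(block, (0.0, 1.0)).all():
                continue
            ref = block.sum(axis=1) == 0.0
            if ref.any():
                s = y[ref].sum()
                if s == 0 or s == ref.sum():
                    dropped.extend(names[j] for j in js)
                    keep = [j for j in range(len(names)) if j not in js]
                    X, names = X[:, keep], [names[j] for j in keep]
                    changed = True
                    break
    return X, names, dropped


def predict_proba(fit: LogisticFit, X: np.ndarray) -> np.ndarray:
    return expit(np.asarray(X, dtype=float) @ fit.params)


def wald_test(fit: LogisticFit, term: str) -> tuple[float, float]:
    """Wald z and two-sided p for one term of a fitted model."""
    return fit.wald(term)


__all__ = ["LogisticFit", "irls_logit", "predict_proba", "wald_test", "_Z95"]
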