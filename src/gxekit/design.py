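"""Design-matrix construction from a cohort table.

Terms are either column names (categorical columns expand to indicator
columns against their fixed reference level; anything else enters as a single
continuous column) or interactions written ``"a:b"`` (all pairwise products
of the two expansions).  An intercept column is always first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import CATEGORICAL_LEVELS, dummy_name
from .errors import ConfigurationError

# quartile factor shares the categorical machinery; Q1 = reference
_LEVELS = dict(CATEGORICAL_LEVELS)
_LEVELS["prs_quartile"] = ["Q1", "Q2", "Q3", "Q4"]

TermSpec = str


def _expand_single(cohort: pd.DataFrame, name: str) -> list[tuple[str, np.ndarray]]:
    if name not in cohort.columns:
        raise ConfigurationError(f"cohort is missing column {name!r}")
    if name in _LEVELS:
        col = cohort[name].astype(str)
        levels = _LEVELS[name]
        bad = set(col.unique()) - set(levels)
        if bad:
            raise ConfigurationError(f"column {name!r} has unknown levels {sorted(bad)}")
        present = set(col.unique())
        # levels absent from the data would give all-zero columns; drop them
        return [(dummy_name(name, lev), (col == lev).to_numpy(dtype=float))
                for lev in levels[1:] if lev in present]
    vals = pd.to_numeric(cohort[name], errors="coerce").to_numpy(dtype=float)
    return [(name, vals)]


def expand_term(cohort: pd.DataFrame, term: TermSpec) -> list[tuple[str, np.ndarray]]:
    """Expand one term into named design columns."""
    if ":" in term:
        left, right = term.split(":", 1)
        out = []
        for ln, lv in expand_term(cohort, left):
            for rn, rv in expand_term(cohort, right):
                out.append((f"{ln}:{rn}", lv * rv))
        return out
    return _expand_single(cohort, term)


def build_design(cohort: pd.DataFrame, terms: list[TermSpec]) -> tuple[np.ndarray, list[str]]:
    """Build (X, names) with a leading intercept column."""
    names = ["intercept"]
    cols = [np.ones(len(cohort))]
    for term in terms:
        for n, v in expand_term(cohort, term):
            names.append(n)
            cols.append(v)
    return np.column_stack(cols), names
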