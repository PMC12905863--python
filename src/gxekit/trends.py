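"""Per-participant pollutant trend slopes and descriptive summaries.

The exposure metric is the ordinary-least-squares slope of annual mean
concentration on time over the years preceding recruitment:
``conc_t = beta0 + beta1 * t + e_t``.  Years are recoded to 0..(n-1), 0 being
the earliest year in the window, so ``beta0`` is the fitted concentration at
window start and ``beta1`` is in concentration units per year; a positive
slope means worsening air quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InsufficientDataError

log = logging.getLogger(__name__)

POLLUTANTS = ("pm25", "no2", "so2", "o3")


@dataclass(frozen=True)
class SlopeResult:
    participant_id: str
    pollutant: str
    beta0: float        # fitted concentration at window start
    beta1: float        # annual rate of change (unit per year)
    n_years: int
    baseline: float     # annual mean in the index (latest) year


def fit_slope(series: Iterable[tuple[float, float]],
              participant_id: str = "", pollutant: str = "") -> SlopeResult:
    """OLS slope of concentration on time for one participant/pollutant series.

    ``series`` is (year, concentration) pairs; years are shifted so the
    earliest is 0 before fitting.  Requires >= 2 distinct years.
    """
    pairs = list(series)
    if len(pairs) < 2:
        raise InsufficientDataError(f"need >= 2 annual values, got {len(pairs)}")
    t = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.unique(t).size < 2:
        raise DegenerateDesignError("all years identical; slope undefined")
    t = t - t.min()
    tbar, ybar = t.mean(), y.mean()
    dt = t - tbar
    beta1 = float(np.dot(dt, y - ybar) / np.dot(dt, dt))
    beta0 = float(ybar - beta1 * tbar)
    baseline = float(y[np.argmax(t)])
    return SlopeResult(participant_id, pollutant, beta0, beta1, len(pairs), baseline)


def slope_table(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one slope per (participant, pollutant) from a long-format panel.

    ``panel`` has columns participant_id, pollutant, year, concentration.
    Returns ``(slopes, skipped)``: slopes has one row per fitted series with
    beta0/beta1/n_years/baseline; skipped lists series with < 2 distinct years
    and the reason.
    """
    required = {"participant_id", "pollutant", "year", "concentration"}
    missing = required - set(panel.columns)
    if missing:
        raise InsufficientDataError(f"panel missing columns: {sorted(missing)}")
    if panel.empty:
        log.warning("empty exposure panel: no slopes fitted")
        cols = ["participant_id", "pollutant", "beta0", "beta1", "n_years", "baseline"]
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=["participant_id", "pollutant", "reason"])

    # vectorised per-group OLS via sufficient statistics (no Python loop):
    # beta1 = (S_ty - S_t S_y / n) / (S_tt - S_t^2 / n) with t = year - min(year)
    df = panel.dropna(subset=["concentration"]).copy()
    keys = ["participant_id", "pollutant"]
    grp = df.groupby(keys, sort=True)
    df["t"] = df["year"] - grp["year"].transform("min")
    df["ty"] = df["t"] * df["concentration"]
    df["tt"] = df["t"] * df["t"]
    agg = df.groupby(keys, sort=True).agg(
        n=("t", "size"), n_years=("year", "nunique"),
        st=("t", "sum"), sy=("concentration", "sum"),
        sty=("ty", "sum"), stt=("tt", "sum"),
    ).reset_index()
    # baseline: concentration observed in the latest year of each series
    last = df.sort_values(keys + ["t"]).groupby(keys, sort=True).tail(1)
    agg = agg.merge(last[keys + ["concentration"]].rename(columns={"concentration": "baseline"}),
                    on=keys)
    ok = agg["n_years"] >= 2
    skipped = agg.loc[~ok, keys].copy()
    skipped["reason"] = [f"{k} distinct year(s) < 2" for k in agg.loc[~ok, "n_years"]]
    out = agg.loc[ok].copy()
    denom = out["stt"] - out["st"] ** 2 / out["n"]
    out["beta1"] = (out["sty"] - out["st"] * out["sy"] / out["n"]) / denom
    out["beta0"] = (out["sy"] - out["beta1"] * out["st"]) / out["n"]
    cols = ["participant_id", "pollutant", "beta0", "beta1", "n_years", "baseline"]
    if len(skipped):
        log.warning("skipped %d participant/pollutant series with < 2 years", len(skipped))
    return (out[cols].reset_index(drop=True),
            skipped.reset_index(drop=True)[["participant_id", "pollutant", "reason"]])


def slopes_wide(slopes: pd.DataFrame, value: str = "beta1") -> pd.DataFrame:
    """Pivot the slope table to participant_id x pollutant columns '<pol>_slope'."""
    wide = slopes.pivot(index="participant_id", columns="pollutant", values=value)
    wide.columns = [f"{c}_slope" for c in wide.columns]
    return wide.reset_index()


def describe(values: Sequence[float]) -> dict[str, float]:
    """Mean/SD/median/min/max/Q1/Q3/IQR summary (sample SD, linear-interpolation quantiles)."""
    x = np.asarray(list(values), dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise InsufficientDataError("cannot summarise an empty list")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "median": float(med),
        "min": float(x.min()),
        "max": float(x.max()),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }


def exposure_summary_table(panel: pd.DataFrame, slopes: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table of baselines and slopes, one row per pollutant x metric."""
    rows = []
    for pol in sorted(slopes["pollutant"].unique()):
        sub = slopes[slopes["pollutant"] == pol]
        for metric, vals in (("baseline", sub["baseline"]), ("slope", sub["beta1"])):
            d = describe(vals)
            d.update({"pollutant": pol, "metric": metric})
            rows.append(d)
    cols = ["pollutant", "metric", "n", "mean", "sd", "median", "min", "max", "q1", "q3", "iqr"]
    return pd.DataFrame(rows)[cols]
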