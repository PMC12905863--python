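"""End-to-end orchestration: simulate/ingest -> QC -> slopes -> PRS -> models.

One :func:`run_pipeline` call produces the five study-shaped tables
(descriptives with level-wise odds ratios; slope descriptives; pollutant
slope models; PRS quartile models; slope-by-PRS interaction with RERI), an
exclusion report, a JSON run manifest (package versions, seed, config hash)
and a log.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import io as gio
from .association import chisq_test, model_suite, two_by_two_or
from .config import ClumpParams, OutcomeCoefs, QCParams, SimulationConfig, config_to_dict
from .covariates import CATEGORICAL_LEVELS, MODEL1_COVARIATES
from .errors import ConfigurationError, InsufficientDataError, UndefinedORError
from .interaction import interaction_fit, reri_bootstrap
from .prs import qc_individuals, qc_variants, subset, threshold_scan
from .simulate import SimDataset, simulate_study
from .trends import exposure_summary_table, slope_table, slopes_wide

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration (simulate-mode or file inputs)."""

    out_dir: str = "gxe_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    # file-input mode (used when ``simulate`` is None)
    dosage_path: str | None = None
    variants_path: str | None = None
    sumstats_path: str | None = None
    exposures_path: str | None = None
    cohort_path: str | None = None
    qc: QCParams = field(default_factory=QCParams)
    clump: ClumpParams = field(default_factory=ClumpParams)
    adjustments: tuple[str, ...] = ("crude", "model1", "model2")
    n_boot: int = 200
    reri_formula: str = "standard"
    interaction_mode: str = "joint"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate is None:
            paths = [self.dosage_path, self.variants_path, self.sumstats_path,
                     self.exposures_path, self.cohort_path]
            if any(p is None for p in paths):
                raise ConfigurationError("either a simulate block or all five input paths are required")
            for p in paths:
                if not Path(p).exists():
                    raise ConfigurationError(f"input path does not exist: {p}")


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        oc = sim.pop("outcome_coefs", None)
        if oc is not None:
            sim["outcome_coefs"] = OutcomeCoefs(**oc)
        for tup_key in ("years", "maf_range"):
            if tup_key in sim:
                sim[tup_key] = tuple(sim[tup_key])
        sim = SimulationConfig(**sim)
    qc = QCParams(**raw.pop("qc", {}))
    clump = raw.pop("clump", {})
    if "p_thresholds" in clump:
        clump["p_thresholds"] = tuple(clump["p_thresholds"])
    clump = ClumpParams(**clump)
    if "adjustments" in raw:
        raw["adjustments"] = tuple(raw["adjustments"])
    return RunConfig(simulate=sim, qc=qc, clump=clump, **raw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# descriptive table

def table1_report(cohort: pd.DataFrame, outcome: str = "t2d") -> pd.DataFrame:
    """Case/non-case descriptive table: counts, column %, level-wise ORs, chi-square p.

    Each categorical variable contributes one row per level; odds ratios are
    2x2 cross-products of each level against the variable's reference level.
    """
    if cohort.empty:
        raise InsufficientDataError("empty cohort")
    y = cohort[outcome].astype(int)
    n_case, n_ctrl = int((y == 1).sum()), int((y == 0).sum())
    rows = [{"variable": "prevalence", "level": "",
             "n_cases": n_case, "pct_cases": 100.0 * n_case / len(y),
             "n_controls": n_ctrl, "pct_controls": 100.0 * n_ctrl / len(y),
             "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_chisq": np.nan}]
    variables = [v for v in CATEGORICAL_LEVELS if v in cohort.columns]
    if "prs_quartile" in cohort.columns:
        variables.append("prs_quartile")
    for var in variables:
        levels = (CATEGORICAL_LEVELS.get(var) or ["Q1", "Q2", "Q3", "Q4"])
        levels = [l for l in levels if (cohort[var] == l).any()]
        counts = pd.crosstab(cohort[var], y).reindex(levels).fillna(0).astype(int)
        table = counts.to_numpy().T  # outcome x level
        p = np.nan
        if len(levels) >= 2 and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            _, _, p = chisq_test(table)
        ref = levels[0]
        b = int(counts.loc[ref].get(1, 0))
        d = int(counts.loc[ref].get(0, 0))
        for lev in levels:
            a = int(counts.loc[lev].get(1, 0))
            c = int(counts.loc[lev].get(0, 0))
            if lev == ref or len(levels) < 2:
                or_, lo, hi = np.nan, np.nan, np.nan
            else:
                try:
                    r = two_by_two_or(a, b, c, d)
                    or_, lo, hi = r.or_, r.ci_low, r.ci_high
                except UndefinedORError:
                    or_, lo, hi = np.nan, np.nan, np.nan
            rows.append({"variable": var, "level": lev if lev != ref else f"{lev} (ref)",
                         "n_cases": a, "pct_cases": 100.0 * a / n_case if n_case else np.nan,
                         "n_controls": c, "pct_controls": 100.0 * c / n_ctrl if n_ctrl else np.nan,
                         "or": or_, "ci_low": lo, "ci_high": hi, "p_chisq": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline

def _ingest(config: RunConfig) -> SimDataset:
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        return simulate_study(sim_cfg)
    genotypes = gio.read_dosage_tsv(config.dosage_path, config.variants_path)
    return SimDataset(
        config=None, genotypes=genotypes,
        sumstats=gio.read_sumstats(config.sumstats_path),
        exposures=gio.read_exposures(config.exposures_path),
        cohort=gio.read_cohort(config.cohort_path), truth=None,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Returns the manifest dict.  On a stage failure, partial outputs are kept,
    the failing stage is named in the manifest, and the error re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gxekit")
    root.addHandler(fh)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest = {
        "package": "gxekit", "version": _pkg_version,
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed, "config_hash": config_hash(config),
        "config": config_to_dict(config), "stages": [], "failed_stage": None,
    }
    stage = "ingest"
    try:
        t0 = time.perf_counter()
        data = _ingest(config)
        manifest["stages"].append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3)})

        stage = "qc"
        t0 = time.perf_counter()
        pid_index = {p: i for i, p in enumerate(data.genotypes.samples)}
        y_all = (data.cohort.set_index("participant_id").loc[data.genotypes.samples, "t2d"]
                 .to_numpy(dtype=int))
        keep_ind, ind_report = qc_individuals(data.genotypes, config.qc)
        g_ind = subset(data.genotypes, individuals=keep_ind)
        keep_var, var_report = qc_variants(g_ind, y_all[keep_ind], config.qc)
        genotypes = subset(g_ind, variants=keep_var)
        ind_report.to_csv(out / "qc_individuals.tsv", sep="\t", index=False)
        var_report.to_csv(out / "qc_variants.tsv", sep="\t", index=False)
        kept_ids = set(genotypes.samples)
        cohort = data.cohort[data.cohort["participant_id"].isin(kept_ids)].reset_index(drop=True)
        panel = data.exposures[data.exposures["participant_id"].isin(kept_ids)]
        log.info("QC kept %d/%d individuals, %d/%d variants",
                 len(keep_ind), data.genotypes.n_individuals,
                 len(keep_var), data.genotypes.n_variants)
        manifest["stages"].append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3),
                                   "n_individuals": len(keep_ind), "n_variants": len(keep_var)})

        stage = "slopes"
        t0 = time.perf_counter()
        slopes, skipped = slope_table(panel)
        cohort = cohort.merge(slopes_wide(slopes), on="participant_id", how="inner")
        table2 = exposure_summary_table(panel, slopes)
        table2.to_csv(out / "table2.tsv", sep="\t", index=False)
        if not skipped.empty:
            skipped.to_csv(out / "slopes_skipped.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3)})

        stage = "prs"
        t0 = time.perf_counter()
        order = cohort["participant_id"].tolist()
        genotypes = subset(genotypes, individuals=np.asarray(
            [genotypes.samples.index(p) for p in order]))
        prs_res = threshold_scan(genotypes, data.sumstats, cohort, config.clump,
                                 covariate_terms=MODEL1_COVARIATES)
        cohort["prs_raw"] = prs_res.scores_raw
        cohort["prs_mean"] = prs_res.scores_mean
        cohort["prs_quartile"] = prs_res.quartile
        prs_res.scan.to_csv(out / "prs_scan.tsv", sep="\t", index=False)
        cohort[["participant_id", "prs_raw", "prs_mean", "prs_quartile"]].to_csv(
            out / "prs_scores.tsv", sep="\t", index=False)
        # analysis-ready cohort (covariates + slopes + PRS) for ad-hoc reanalysis
        cohort.to_csv(out / "analysis_cohort.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3),
                                   "threshold": prs_res.threshold,
                                   "n_variants": prs_res.n_variants,
                                   "delta_auc": prs_res.delta_auc})

        stage = "association"
        t0 = time.perf_counter()
        table1_report(cohort).to_csv(out / "table1.tsv", sep="\t", index=False, float_format="%.6g")
        slope_cols = [c for c in cohort.columns if c.endswith("_slope")]
        table3 = model_suite(cohort, slope_cols, list(config.adjustments))
        table3.to_csv(out / "table3.tsv", sep="\t", index=False, float_format="%.6g")
        table4 = model_suite(cohort, ["prs_quartile"], list(config.adjustments))
        table4.to_csv(out / "table4.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"].append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3)})

        stage = "interaction"
        t0 = time.perf_counter()
        t5_rows, wald_rows = [], []
        for k, col in enumerate(slope_cols):
            ia = interaction_fit(cohort, col, "model1", config.interaction_mode)
            reris = reri_bootstrap(cohort, col, "model1", n_boot=config.n_boot,
                                   seed=config.seed + 1000 + k,
                                   formula_variant=config.reri_formula)
            rmap = {r.prs_category: r for r in reris}
            for _, row in ia.per_quartile.iterrows():
                q = row["prs_category"]
                r = rmap.get(q)
                t5_rows.append({
                    "pollutant": col.replace("_slope", ""), "prs_category": q,
                    "or": row["or"], "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                    "reri": r.estimate if r else np.nan,
                    "reri_ci_low": r.ci_low if r else np.nan,
                    "reri_ci_high": r.ci_high if r else np.nan,
                    "formula_variant": config.reri_formula,
                })
            if ia.products is not None:
                for _, prow in ia.products.iterrows():
                    wald_rows.append({"pollutant": col.replace("_slope", ""),
                                      "term": prow["term"], "z": prow["z"], "p": prow["p"]})
        pd.DataFrame(t5_rows).to_csv(out / "table5.tsv", sep="\t", index=False, float_format="%.6g")
        pd.DataFrame(wald_rows).to_csv(out / "interaction_wald.tsv", sep="\t",
                                       index=False, float_format="%.6g")
        manifest["stages"].append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3)})
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        root.removeHandler(fh)
        fh.close()
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    root.removeHandler(fh)
    fh.close()
    return manifest


def simulate_to_dir(sim_config: SimulationConfig, out_dir, seed: int | None = None) -> SimDataset:
    """Generate a synthetic study and write all interchange files."""
    if seed is not None:
        sim_config = dataclasses.replace(sim_config, seed=seed)
    data = simulate_study(sim_config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_dosage_tsv(data.genotypes, out / "dosages.tsv", out / "variants.tsv")
    gio.write_vcf(data.genotypes, out / "genotypes.vcf")
    gio.write_sumstats(data.sumstats, out / "sumstats.tsv")
    gio.write_exposures(data.exposures, out / "exposures.tsv")
    gio.write_cohort(data.cohort, out / "cohort.tsv")
    gio.write_truth(data.truth, out / "truth.json")
    return data
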