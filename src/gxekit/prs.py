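"""Genotype QC and clumping-and-thresholding polygenic risk scores.

The score is ``PRS_i = sum_j beta_j * G_ij`` over variants kept by a greedy,
p-value-ordered clumping pass (within a 250-kb window, correlated variants
with r^2 above the cutoff are assigned to the most significant one) at a
given p-value threshold.  The working threshold is chosen by scanning a grid
and keeping the model with the largest gain in AUC over the covariate-only
null (ties to the smaller threshold).  Quality control mirrors standard
array-data practice: per-variant and per-individual missingness, minor
allele frequency, an exact Hardy--Weinberg test stratified by case status,
heterozygosity outliers, method-of-moments relatedness (pi-hat) and
principal-component ancestry outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.metrics import roc_auc_score

from .config import ClumpParams, QCParams
from .design import build_design
from .errors import (
    AlignmentError,
    DegenerateCategorizationError,
    InsufficientDataError,
)
from .logistic import drop_quasi_separated, irls_logit, predict_proba
from .simulate import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy--Weinberg test.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities of configurations as or less probable than the
    observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise InsufficientDataError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise InsufficientDataError("no genotype observations")
    n_a = 2 * n_aa + n_Aa          # allele 'a' count
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # per-config log-probability conditional on allele counts
    n_hom_rare = (rare - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logp = (gammaln(n + 1) - gammaln(n_hom_rare + 1) - gammaln(hets + 1)
            - gammaln(n_hom_common + 1) + hets * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_A + 1) - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_Aa
    p_obs = p[hets == obs]
    if p_obs.size == 0:    # inconsistent het parity cannot occur with valid counts
        raise InsufficientDataError("inconsistent genotype counts")
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# variant QC

def qc_variants(genotypes: GenotypeMatrix, outcome: np.ndarray,
                params: QCParams | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Filter variants on missingness, MAF and case/control-stratified HWE.

    Returns (kept variant indices, per-variant report with failure reasons).
    """
    params = params or QCParams()
    y = np.asarray(outcome).astype(int)
    if y.shape[0] != genotypes.n_individuals:
        raise AlignmentError("outcome not aligned to genotype individuals")
    g = genotypes.dosages
    n = genotypes.n_individuals
    miss = (g == MISSING).mean(axis=0)
    freq = genotypes.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isfinite(maf), maf, 0.0)

    cases, controls = y == 1, y == 0
    rep_rows = []
    keep = []
    for j in range(genotypes.n_variants):
        reasons = []
        if miss[j] > params.max_missing_rate:
            reasons.append(f"missingness {miss[j]:.4f} > {params.max_missing_rate}")
        if maf[j] < params.min_maf:
            reasons.append(f"maf {maf[j]:.4f} < {params.min_maf}")
        p_case = p_ctrl = np.nan
        gj = g[:, j]
        for label, mask, thr in (("cases", cases, params.hwe_p_cases),
                                 ("controls", controls, params.hwe_p_controls)):
            sub = gj[mask]
            sub = sub[sub != MISSING]
            if sub.size == 0:
                continue
            pv = hwe_exact_p(int((sub == 0).sum()), int((sub == 1).sum()), int((sub == 2).sum()))
            if label == "cases":
                p_case = pv
            else:
                p_ctrl = pv
            if pv < thr:
                reasons.append(f"hwe_{label} {pv:.3e} < {thr:.0e}")
        rep_rows.append({
            "variant_id": genotypes.variants["variant_id"].iloc[j],
            "missing_rate": miss[j], "maf": maf[j],
            "hwe_p_cases": p_case, "hwe_p_controls": p_ctrl,
            "excluded": bool(reasons), "reasons": ";".join(reasons),
        })
        if not reasons:
            keep.append(j)
    if not keep:
        log.warning("variant QC excluded every variant")
    return np.asarray(keep, dtype=int), pd.DataFrame(rep_rows)


# ---------------------------------------------------------------------------
# individual QC

def _onehot(g: np.ndarray) -> tuple[np.ndarray, ...]:
    return tuple((g == k).astype(np.float64) for k in (0, 1, 2))


def pihat_matrix(genotypes: GenotypeMatrix) -> np.ndarray:
    """PLINK-style method-of-moments IBD pi-hat for every individual pair.

    IBS counts use pairwise-complete variants (one-hot dot products); the
    expected IBS composition under IBD states uses the sample allele
    frequencies.  Estimates are clipped to [0, 1].
    """
    g = genotypes.dosages
    A0, A1, A2 = _onehot(g)
    valid = (g != MISSING).astype(np.float64)
    ibs0 = A0 @ A2.T + A2 @ A0.T
    ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    n_shared = valid @ valid.T
    ibs1 = n_shared - ibs0 - ibs2

    p = genotypes.allele_freq()
    p = np.where(np.isfinite(p), np.clip(p, 1e-6, 1 - 1e-6), 0.5)
    q = 1.0 - p
    w0_ibd0 = 2 * p**2 * q**2
    w1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    w2_ibd0 = 1.0 - w0_ibd0 - w1_ibd0
    w1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    w2_ibd1 = 1.0 - w1_ibd1
    # per-pair expectations restricted to pairwise-complete variants
    E = {k: valid @ (valid * w).T for k, w in
         (("00", w0_ibd0), ("10", w1_ibd0), ("20", w2_ibd0), ("11", w1_ibd1), ("21", w2_ibd1))}

    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = ibs0 / E["00"]
        z1 = (ibs1 - z0 * E["10"]) / E["11"]
        z2 = (ibs2 - z0 * E["20"] - z1 * E["21"]) / np.where(n_shared > 0, n_shared, np.nan)
    z0, z1, z2 = (np.nan_to_num(z, nan=0.0) for z in (z0, z1, z2))
    pihat = np.clip(0.5 * z1 + z2, 0.0, 1.0)
    np.fill_diagonal(pihat, 1.0)
    return pihat


def pc_scores(genotypes: GenotypeMatrix, n_components: int = 2) -> np.ndarray:
    """Top principal-component scores of the standardized, mean-imputed dosages."""
    g = genotypes.dosage_float()
    mu = np.nanmean(g, axis=0)
    idx = np.where(np.isnan(g))
    g[idx] = mu[idx[1]]
    g -= mu
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    g /= sd
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    return u[:, :n_components] * s[:n_components]


def qc_individuals(genotypes: GenotypeMatrix,
                   params: QCParams | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Filter individuals on missingness, heterozygosity, relatedness and PCs.

    Within a related pair (pi-hat > threshold) the member with the higher
    missingness is dropped (ties to the larger index).  Returns (kept
    individual indices, per-individual report).
    """
    params = params or QCParams()
    g = genotypes.dosages
    n = genotypes.n_individuals
    called = g != MISSING
    n_called = called.sum(axis=1)
    miss = 1.0 - n_called / genotypes.n_variants
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, (g == 1).sum(axis=1) / n_called, np.nan)
    het_mu, het_sd = np.nanmean(het), np.nanstd(het)

    reasons: list[list[str]] = [[] for _ in range(n)]
    for i in np.flatnonzero(miss > params.max_missing_rate):
        reasons[i].append(f"missingness {miss[i]:.4f} > {params.max_missing_rate}")
    if het_sd > 0:
        for i in np.flatnonzero(np.abs(het - het_mu) > params.het_sd * het_sd):
            reasons[i].append(f"heterozygosity {het[i]:.4f} outside mean±{params.het_sd}SD")

    pihat_max = np.zeros(n)
    if genotypes.n_variants < params.min_ibd_markers:
        # method-of-moments IBD is far too noisy on few markers: at the 0.2
        # cutoff its sampling error would flag large fractions of unrelated
        # pairs, so the screen is skipped rather than silently misapplied
        log.warning("relatedness check skipped: %d markers < min_ibd_markers=%d",
                    genotypes.n_variants, params.min_ibd_markers)
    elif n >= 2:
        ph = pihat_matrix(genotypes)
        np.fill_diagonal(ph, 0.0)
        pihat_max = ph.max(axis=1)
        alive = np.array([not r for r in reasons])
        ii, jj = np.where(np.triu(ph > params.max_pihat, k=1))
        for i, j in zip(ii, jj):
            if not (alive[i] and alive[j]):
                continue
            drop = j if (miss[j], j) >= (miss[i], i) else i
            reasons[drop].append(f"pi-hat {ph[i, j]:.3f} > {params.max_pihat} with index {i if drop == j else j}")
            alive[drop] = False
    else:
        log.warning("fewer than 2 individuals: relatedness check skipped")

    pcs = pc_scores(genotypes)
    mu, sd = pcs.mean(axis=0), pcs.std(axis=0)
    sd[sd == 0] = np.inf
    out = np.abs(pcs - mu) > params.pc_outlier_sd * sd
    for i in np.flatnonzero(out.any(axis=1)):
        reasons[i].append(f"PC outlier beyond {params.pc_outlier_sd} SD")

    report = pd.DataFrame({
        "sample": genotypes.samples,
        "missing_rate": miss, "het_rate": het, "max_pihat": pihat_max,
        "pc1": pcs[:, 0], "pc2": pcs[:, 1],
        "excluded": [bool(r) for r in reasons],
        "reasons": [";".join(r) for r in reasons],
    })
    keep = np.flatnonzero(~report["excluded"].to_numpy())
    return keep, report


def subset(genotypes: GenotypeMatrix, individuals: np.ndarray | None = None,
           variants: np.ndarray | None = None) -> GenotypeMatrix:
    """Restrict a genotype matrix to the given individual/variant indices."""
    dos = genotypes.dosages
    samples = genotypes.samples
    var = genotypes.variants
    if individuals is not None:
        dos = dos[individuals]
        samples = [samples[i] for i in individuals]
    if variants is not None:
        dos = dos[:, variants]
        var = var.iloc[variants].reset_index(drop=True)
    return GenotypeMatrix(dos.copy(), var, samples)


# ---------------------------------------------------------------------------
# allele alignment

@dataclass
class AlignedEffects:
    """Summary-stat effects mapped onto genotype variants."""

    variant_idx: np.ndarray          # indices into the genotype variant axis
    beta: np.ndarray                 # effect per counted (effect) allele
    flipped: np.ndarray              # True where the genotype alt != effect allele
    pvalue: np.ndarray
    dropped: pd.DataFrame            # variant_id, reason

    def __len__(self) -> int:
        return self.variant_idx.size


def align_alleles(genotypes: GenotypeMatrix, sumstats: pd.DataFrame) -> AlignedEffects:
    """Match summary statistics to genotype variants and orient effect alleles.

    Matching is by variant_id when both sides carry one, else by (chrom, pos).
    Where the genotype's counted (alt) allele equals the effect allele the
    effect is used as-is; where it equals the other allele the dosage sense
    is flipped.  Strand-ambiguous (A/T, C/G) and allele-incompatible variants
    are dropped with a reason.
    """
    v = genotypes.variants
    if "variant_id" in sumstats.columns and sumstats["variant_id"].notna().all():
        gmap = {vid: j for j, vid in enumerate(v["variant_id"])}
        keys = sumstats["variant_id"]
    else:
        gmap = {(c, int(p)): j for j, (c, p) in enumerate(zip(v["chrom"], v["pos"]))}
        keys = list(zip(sumstats["chrom"].astype(str), sumstats["pos"].astype(int)))

    idx, beta, flipped, pval, dropped = [], [], [], [], []
    for k, row in zip(keys, sumstats.itertuples(index=False)):
        j = gmap.get(k)
        if j is None:
            dropped.append({"variant_id": getattr(row, "variant_id", str(k)), "reason": "not in genotypes"})
            continue
        ea, oa = str(row.effect_allele), str(row.other_allele)
        if frozenset((ea, oa)) in AMBIGUOUS_PAIRS:
            dropped.append({"variant_id": v["variant_id"].iloc[j], "reason": "strand-ambiguous (A/T or C/G)"})
            continue
        ref, alt = v["ref"].iloc[j], v["alt"].iloc[j]
        if {ea, oa} != {ref, alt}:
            dropped.append({"variant_id": v["variant_id"].iloc[j], "reason": f"alleles {ea}/{oa} incompatible with {ref}/{alt}"})
            continue
        idx.append(j)
        beta.append(float(row.beta))
        flipped.append(ea != alt)
        pval.append(float(row.pvalue))
    return AlignedEffects(
        np.asarray(idx, dtype=int), np.asarray(beta), np.asarray(flipped, dtype=bool),
        np.asarray(pval), pd.DataFrame(dropped, columns=["variant_id", "reason"]),
    )


# ---------------------------------------------------------------------------
# clumping and scoring

def _effect_dosage(genotypes: GenotypeMatrix, aligned: AlignedEffects) -> np.ndarray:
    """Float dosage of the effect allele (NaN missing), flipping where needed."""
    d = genotypes.dosage_float()[:, aligned.variant_idx]
    d[:, aligned.flipped] = 2.0 - d[:, aligned.flipped]
    return d


def _pairwise_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of x with each column of Y, pairwise-complete."""
    out = np.zeros(Y.shape[1])
    for k in range(Y.shape[1]):
        m = np.isfinite(x) & np.isfinite(Y[:, k])
        if m.sum() < 2:
            continue
        a, b = x[m], Y[m, k]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
        out[k] = r * r
    return out


def ld_clump(genotypes: GenotypeMatrix, aligned: AlignedEffects,
             params: ClumpParams | None = None, threshold: float = 0.5) -> np.ndarray:
    """Greedy p-ordered clumping; returns positions into ``aligned`` of the index variants.

    Variants with p <= threshold are visited in ascending p order (ties by
    position then id, for determinism); each still-unassigned variant becomes
    an index and absorbs every unassigned variant within ``window_kb`` whose
    in-sample dosage r^2 with it is >= ``r2_threshold``.
    """
    params = params or ClumpParams()
    v = genotypes.variants
    cand = np.flatnonzero(aligned.pvalue <= threshold)
    if cand.size == 0:
        return np.asarray([], dtype=int)
    pos = v["pos"].to_numpy()[aligned.variant_idx[cand]]
    chrom = v["chrom"].to_numpy()[aligned.variant_idx[cand]]
    vid = v["variant_id"].to_numpy()[aligned.variant_idx[cand]]
    order = np.lexsort((vid, pos, aligned.pvalue[cand]))
    dos = _effect_dosage(genotypes, aligned)[:, cand]

    window = params.window_kb * 1000.0
    available = np.ones(cand.size, dtype=bool)
    index_set = []
    for o in order:
        if not available[o]:
            continue
        available[o] = False
        index_set.append(cand[o])
        near = available & (chrom == chrom[o]) & (np.abs(pos - pos[o]) <= window)
        near_idx = np.flatnonzero(near)
        if near_idx.size:
            r2 = _pairwise_r2(dos[:, o], dos[:, near_idx])
            available[near_idx[r2 >= params.r2_threshold]] = False
    return np.asarray(sorted(index_set), dtype=int)


def score(genotypes: GenotypeMatrix, aligned: AlignedEffects,
          subset_pos: np.ndarray | None = None) -> np.ndarray:
    """Per-individual raw PRS ``sum_j beta_j G_ij`` over the retained variants.

    Missing dosages are imputed as twice the sample effect-allele frequency.
    """
    if subset_pos is not None:
        aligned = AlignedEffects(aligned.variant_idx[subset_pos], aligned.beta[subset_pos],
                                 aligned.flipped[subset_pos], aligned.pvalue[subset_pos],
                                 aligned.dropped)
    if len(aligned) == 0:
        log.warning("scoring with zero retained variants: all scores are 0")
        return np.zeros(genotypes.n_individuals)
    d = _effect_dosage(genotypes, aligned)
    mu = np.nanmean(d, axis=0)           # = 2 * effect-allele frequency
    idx = np.where(np.isnan(d))
    d[idx] = np.where(np.isfinite(mu), mu, 0.0)[idx[1]]
    return d @ aligned.beta


def quartile_categories(scores: np.ndarray) -> np.ndarray:
    """Quartile label per individual; cut points are the cohort 25/50/75th
    percentiles, intervals right-closed (a score equal to a cut point falls
    in the lower category)."""
    s = np.asarray(scores, dtype=float)
    if np.unique(s).size < 4:
        raise DegenerateCategorizationError("need >= 4 distinct scores for quartiles")
    c25, c50, c75 = np.percentile(s, [25, 50, 75])
    k = (s > c25).astype(int) + (s > c50) + (s > c75)
    return np.asarray([f"Q{i + 1}" for i in k])


# ---------------------------------------------------------------------------
# threshold scan

@dataclass
class PRSResult:
    """Chosen polygenic score with its threshold-scan diagnostics."""

    scores_raw: np.ndarray
    scores_mean: np.ndarray              # raw / (2 * n_variants)
    quartile: np.ndarray
    threshold: float
    n_variants: int
    delta_auc: float
    pseudo_r2: float
    scan: pd.DataFrame = field(repr=False)


def threshold_scan(genotypes: GenotypeMatrix, sumstats: pd.DataFrame,
                   cohort: pd.DataFrame, params: ClumpParams | None = None,
                   covariate_terms: list[str] | None = None,
                   outcome: str = "t2d") -> PRSResult:
    """Clump+score at every p threshold; keep the one maximising delta-AUC.

    delta-AUC is the AUC of ``outcome ~ covariates + z(PRS)`` minus the AUC
    of the covariate-only null (0.5 when there are no covariates); pseudo-R²
    is Nagelkerke's.  Non-convergent fits are skipped with a warning.
    """
    params = params or ClumpParams()
    covariate_terms = covariate_terms or []
    aligned = align_alleles(genotypes, sumstats)
    y = cohort[outcome].to_numpy(dtype=float)

    Xc, names_c = build_design(cohort, covariate_terms)
    Xc, names_c, sep = drop_quasi_separated(Xc, names_c, y)
    if sep:
        log.warning("dropped quasi-separated indicator column(s): %s", ", ".join(sep))
    if covariate_terms:
        null_fit = irls_logit(Xc, y, terms=names_c)
        null_auc = float(roc_auc_score(y, predict_proba(null_fit, Xc)))
    else:
        null_auc = 0.5

    rows, best = [], None
    for thr in params.p_thresholds:
        keep = ld_clump(genotypes, aligned, params, thr)
        raw = score(genotypes, aligned, subset_pos=keep)
        sd = raw.std()
        row = {"threshold": thr, "n_variants": int(keep.size),
               "delta_auc": np.nan, "pseudo_r2": np.nan}
        if keep.size == 0 or sd == 0 or np.unique(raw).size < 4:
            log.warning("threshold %.3g: no usable PRS (n_variants=%d, too little score variation)",
                        thr, keep.size)
            rows.append(row)
            continue
        z = (raw - raw.mean()) / sd
        X = np.column_stack([Xc, z])
        fit = irls_logit(X, y, terms=names_c + ["prs_z"])
        if not fit.converged:
            log.warning("threshold %.3g skipped: logistic fit did not converge", thr)
            rows.append(row)
            continue
        auc = float(roc_auc_score(y, predict_proba(fit, X)))
        row["delta_auc"] = auc - null_auc
        row["pseudo_r2"] = fit.nagelkerke_r2()
        rows.append(row)
        if best is None or row["delta_auc"] > best[0] + 1e-15:
            best = (row["delta_auc"], thr, keep, raw, row["pseudo_r2"])

    scan = pd.DataFrame(rows)
    if best is None:
        raise InsufficientDataError("no threshold produced a usable PRS")
    dauc, thr, keep, raw, pr2 = best
    return PRSResult(
        scores_raw=raw,
        scores_mean=raw / (2.0 * keep.size),
        quartile=quartile_categories(raw),
        threshold=float(thr), n_variants=int(keep.size),
        delta_auc=float(dauc), pseudo_r2=float(pr2), scan=scan,
    )
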