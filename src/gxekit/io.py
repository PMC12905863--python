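"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes travel either as a dosage TSV (rows = individuals, columns =
variant IDs, missing = NA) with a companion variant-metadata TSV, or as an
uncompressed VCF with hard GT calls.  Summary statistics, exposures, cohort
tables and reports are TSV; ground truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeMatrix, GroundTruth

SUMSTAT_COLS = ["chrom", "pos", "variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]


def write_dosage_tsv(genotypes: GenotypeMatrix, dosage_path, variants_path) -> None:
    g = genotypes.dosage_float()
    df = pd.DataFrame(g, index=pd.Index(genotypes.samples, name="participant_id"),
                      columns=genotypes.variants["variant_id"])
    df.to_csv(dosage_path, sep="\t", na_rep="NA", float_format="%.0f")
    genotypes.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, variants_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col="participant_id")
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    dos = df.to_numpy(dtype=float)
    out = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
    return GenotypeMatrix(out, variants, [str(s) for s in df.index])


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with hard GT calls (unphased; missing = ./.)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    v = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for j in range(genotypes.n_variants):
            calls = "\t".join(gt_strings[int(g)] for g in genotypes.dosages[:, j])
            fh.write(f"{v['chrom'].iloc[j]}\t{v['pos'].iloc[j]}\t{v['variant_id'].iloc[j]}\t"
                     f"{v['ref'].iloc[j]}\t{v['alt'].iloc[j]}\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read hard GT calls from a VCF (plain text or bgzipped) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        types = rec.gt_types  # 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        dose = np.select([types == 0, types == 1, types == 3], [0, 1, 2], default=MISSING)
        rows.append(dose.astype(np.int8))
        meta.append({"chrom": rec.CHROM, "pos": rec.POS, "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                     "ref": rec.REF, "alt": rec.ALT[0] if rec.ALT else "."})
    dos = np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(dos, pd.DataFrame(meta), samples)


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats[SUMSTAT_COLS].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_exposures(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_exposures(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "causal_betas": truth.causal_betas.tolist(),
        "true_outcome_coefs": truth.true_outcome_coefs,
        "achieved_prevalence": truth.achieved_prevalence,
        "implied_true_reri": truth.implied_true_reri,
        "true_slopes": truth.true_slopes.to_dict(orient="list") if truth.true_slopes is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
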