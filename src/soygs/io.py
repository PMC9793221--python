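"""Genotype/phenotype readers and writers, MAF filtering, imputation, and
descriptive trait statistics.

Supported genotype dialects
---------------------------
``vcf``
    VCF v4.x, GT field only.  Only biallelic SNPs are loaded; other sites
    are skipped with a logged count.  Coordinates stay 1-based.
``plink_raw``
    The PLINK additive text export (``--recode A``): columns
    FID IID PAT MAT SEX PHENOTYPE then one dosage column per marker named
    ``<marker>_<counted allele>``.  Carries no coordinates, so markers get
    synthetic ones (chrom "0", pos = column index).
``csv``
    Plain dosage matrix: samples in rows, first column sample IDs, header
    row of marker IDs, missing as empty or NA.  Synthetic coordinates as
    for plink_raw.

Phenotypes travel as a two-column TSV (sample_id, value) with a header
naming the trait.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GenotypeMatrix,
    PhenotypeSummary,
    PhenotypeVector,
    PopulationPartition,
)
from .errors import DataError, FormatError, IntegrityError
from .simulate import TruthRecord

logger = logging.getLogger("soygs")

FORMATS = ("vcf", "plink_raw", "csv")


# ---------------------------------------------------------------- genotypes


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    path = Path(path)
    if format not in FORMATS:
        raise FormatError(f"unknown genotype format {format!r}; choose from {FORMATS}")
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    return _read_csv(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = np.asarray(vcf.samples, dtype=str)
    ids, chrom, pos, cols = [], [], [], []
    skipped = 0
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        cols.append(gt)
    if skipped:
        logger.info("read_genotypes(vcf): skipped %d non-biallelic-SNP sites", skipped)
    if not cols:
        raise FormatError(f"no biallelic SNP records in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        marker_ids=np.asarray(ids),
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        dosages=np.column_stack(cols),
    )


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise FormatError(f"cannot parse PLINK raw file {path}: {exc}") from exc
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if df.columns[: len(meta)].tolist() != meta:
        raise FormatError(
            f"{path} line 1: expected PLINK additive header starting {meta}"
        )
    snp_cols = df.columns[len(meta):]
    marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return _with_synthetic_map(
        sample_ids=df["IID"].astype(str).to_numpy(),
        marker_ids=np.asarray(marker_ids),
        dosages=df[snp_cols].to_numpy(dtype=float),
    )


def _read_csv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse dosage CSV {path}: {exc}") from exc
    return _with_synthetic_map(
        sample_ids=df.index.astype(str).to_numpy(),
        marker_ids=df.columns.astype(str).to_numpy(),
        dosages=df.to_numpy(dtype=float),
    )


def _with_synthetic_map(sample_ids, marker_ids, dosages) -> GenotypeMatrix:
    m = len(marker_ids)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=marker_ids,
        chrom=np.full(m, "0"),
        pos=np.arange(1, m + 1),
        dosages=dosages,
    )


def write_genotypes(G: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    path = Path(path)
    if format == "vcf":
        _write_vcf(G, path)
    elif format == "plink_raw":
        df = pd.DataFrame(
            {
                "FID": G.sample_ids,
                "IID": G.sample_ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        dos = pd.DataFrame(
            G.dosages, columns=[f"{m}_A" for m in G.marker_ids]
        )
        pd.concat([df, dos], axis=1).to_csv(path, sep=" ", index=False, na_rep="NA")
    elif format == "csv":
        pd.DataFrame(G.dosages, index=G.sample_ids, columns=G.marker_ids).to_csv(
            path, index_label="sample_id"
        )
    else:
        raise FormatError(f"unknown genotype format {format!r}")


def _write_vcf(G: GenotypeMatrix, path: Path) -> None:
    dos = G.dosages
    finite = dos[np.isfinite(dos)]
    if finite.size and np.any(finite != np.round(finite)):
        raise DataError(
            "VCF output encodes GT calls and requires integer dosages; "
            "write imputed matrices as csv instead"
        )
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=soygs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = []
        for c in G.chrom:
            if c not in seen:
                seen.append(c)
        for c in seen:
            mask = G.chrom == c
            fh.write(f"##contig=<ID={c},length={int(G.pos[mask].max()) + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for k in range(G.n_markers):
            calls = "\t".join(
                "./." if np.isnan(d) else gt_code[float(d)] for d in dos[:, k]
            )
            fh.write(
                f"{G.chrom[k]}\t{G.pos[k]}\t{G.marker_ids[k]}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------- phenotypes


def read_phenotypes(path: str | Path) -> PhenotypeVector:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse phenotype TSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    trait = str(df.columns[1])
    return PhenotypeVector(
        sample_ids=df.iloc[:, 0].astype(str).to_numpy(),
        values=df.iloc[:, 1].to_numpy(dtype=float),
        trait_name=trait,
    )


def write_phenotypes(p: PhenotypeVector, path: str | Path) -> None:
    pd.DataFrame({"sample_id": p.sample_ids, p.trait_name: p.values}).to_csv(
        path, sep="\t", index=False
    )


def write_partition(part: PopulationPartition, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": part.sample_ids, "label": part.labels, "scheme": part.scheme}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> PopulationPartition:
    df = pd.read_csv(path, sep="\t")
    scheme = str(df["scheme"].iloc[0]) if "scheme" in df else "true_simulated"
    return PopulationPartition(
        df["sample_id"].astype(str).to_numpy(), df["label"].to_numpy(), scheme
    )


def write_truth(truth: TruthRecord, G: GenotypeMatrix, path: str | Path) -> None:
    """Truth sidecar: per-QTL rows then per-sample breeding values."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#realized_h2\t{float(truth.realized_h2)!r}\n")
        fh.write("#qtl\tmarker_id\teffect\n")
        for idx, eff in zip(truth.qtl_indices, np.atleast_1d(truth.qtl_effects)):
            fh.write(f"qtl\t{G.marker_ids[idx]}\t{float(np.ravel(eff)[0])!r}\n")
        fh.write("#bv\tsample_id\tbreeding_value\n")
        for sid, bv in zip(G.sample_ids, truth.true_breeding_values):
            fh.write(f"bv\t{sid}\t{float(bv)!r}\n")


# ---------------------------------------------------------------- filters


def maf_filter(G: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop markers with minor allele frequency below ``min_maf``.

    Frequencies are computed over non-missing calls.  The boundary is
    inclusive: MAF exactly equal to ``min_maf`` is retained ("less than 5%"
    is eliminated).  All-missing markers are removed, not an error.
    """
    if G.n_markers == 0:
        raise DataError("empty genotype matrix")
    n_obs = np.sum(~np.isnan(G.dosages), axis=0)
    total = np.nansum(G.dosages, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, total / (2.0 * n_obs), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.where(np.isnan(maf), False, maf >= min_maf)
    removed = int((~keep).sum())
    if removed:
        logger.info("maf_filter: removed %d / %d markers below MAF %.3g",
                    removed, G.n_markers, min_maf)
    return GenotypeMatrix(
        sample_ids=G.sample_ids,
        marker_ids=G.marker_ids[keep],
        chrom=G.chrom[keep],
        pos=G.pos[keep],
        dosages=G.dosages[:, keep],
    )


def impute_missing_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the marker's mean over non-missing calls."""
    D = G.dosages
    if not np.isnan(D).any():
        return G
    n_obs = np.sum(~np.isnan(D), axis=0)
    if np.any(n_obs == 0):
        raise DataError(
            "marker(s) with all calls missing; run maf_filter before imputation"
        )
    col_mean = np.nanmean(D, axis=0)
    filled = np.where(np.isnan(D), col_mean, D)
    return GenotypeMatrix(
        sample_ids=G.sample_ids,
        marker_ids=G.marker_ids,
        chrom=G.chrom,
        pos=G.pos,
        dosages=filled,
    )


# ---------------------------------------------------------------- statistics


def describe_phenotype(p: PhenotypeVector) -> PhenotypeSummary:
    """Eight descriptive statistics of a trait.

    Sample (n-1) SD/variance; skewness and excess kurtosis use the
    bias-corrected sample conventions (the SPSS-style adjusted estimators);
    cv_percent = 100*sd/mean for positive-mean traits.  For a constant
    trait, skewness and kurtosis are undefined and reported as NaN; for a
    non-positive mean, the CV is undefined and reported as NaN.
    """
    x = p.values
    n = len(x)
    if n < 4:
        raise DataError("describe_phenotype requires n >= 4 (kurtosis undefined)")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        skew = kurt = float("nan")
        cv = 0.0 if mean > 0 else float("nan")
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
        cv = 100.0 * sd / mean if mean > 0 else float("nan")
    if mean <= 0:
        logger.warning("describe_phenotype: non-positive mean, CV undefined")
    return PhenotypeSummary(
        n=n,
        min=float(np.min(x)),
        max=float(np.max(x)),
        mean=mean,
        sd=sd,
        variance=sd**2,
        skewness=skew,
        kurtosis=kurt,
        cv_percent=cv,
    )


__all__ = [
    "FORMATS",
    "describe_phenotype",
    "impute_missing_mean",
    "maf_filter",
    "read_genotypes",
    "read_partition",
    "read_phenotypes",
    "write_genotypes",
    "write_partition",
    "write_phenotypes",
    "write_truth",
]
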