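"""On-disk formats for genotypes, summary statistics, phenotypes and scores.

Genotypes travel as PLINK-style ``traw`` text (tab-separated, one row per
variant, dosage = count of the COUNTED allele, missing = ``NA``) or as a
biallelic-SNP subset of VCF.  Summary statistics, phenotype/covariate tables
and score files are plain TSV.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAW_META_COLS = ["CHR", "SNP", "CM", "POS", "COUNTED", "ALT"]

#: required summary-statistics columns (BETA may be replaced by OR; MAF optional)
SUMSTATS_REQUIRED = ["SNP", "CHR", "BP", "A1", "A2", "SE", "P", "N"]

VARIANT_COLS = ["variant_id", "chrom", "pos", "allele_counted", "allele_other"]


class SchemaError(ValueError):
    """A table is missing required columns or has a malformed header."""


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering (1..22 before X/Y/MT, strings last)."""
    num = pd.to_numeric(chrom, errors="coerce")
    special = chrom.astype(str).str.upper().map({"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26})
    return num.fillna(special).fillna(1000)


@dataclass
class GenotypePanel:
    """Samples x variants additive dosage matrix with variant metadata.

    ``dosage`` holds counted-allele counts in {0, 1, 2} with ``nan`` for
    missing.  ``variants`` is a DataFrame with columns ``variant_id, chrom,
    pos, allele_counted, allele_other`` sorted by (chrom, pos).
    """

    variants: pd.DataFrame
    sample_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        missing = [c for c in VARIANT_COLS if c not in self.variants.columns]
        if missing:
            raise SchemaError(f"variant table missing columns: {missing}")
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.variants["variant_id"].duplicated().any():
            dupes = self.variants.loc[self.variants["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant ids: {list(dupes[:5])}")
        self._sort_variants()

    def _sort_variants(self) -> None:
        key = pd.DataFrame(
            {"k": _chrom_sort_key(self.variants["chrom"]), "pos": self.variants["pos"]}
        )
        order = key.sort_values(["k", "pos"], kind="stable").index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            logger.info("variants re-sorted by (chrom, pos)")
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Counted-allele frequency folded to the minor side."""
        freq = self.allele_freq()
        return np.minimum(freq, 1.0 - freq)

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per variant (missing dosages ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_samples(self, ids: list[str]) -> "GenotypePanel":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return GenotypePanel(self.variants.copy(), list(ids), self.dosage[rows])

    def subset_variants(self, variant_ids: list[str]) -> "GenotypePanel":
        keep = self.variants["variant_id"].isin(set(variant_ids)).to_numpy()
        return GenotypePanel(
            self.variants.loc[keep].copy(), list(self.sample_ids), self.dosage[:, keep]
        )

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variants[VARIANT_COLS].equals(other.variants[VARIANT_COLS])
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class PhenotypeTable:
    """Per-sample phenotype plus named covariate columns.

    ``table`` has one row per sample with columns ``sample_id``,
    ``phenotype`` and any covariates.  ``trait_type`` is ``"binary"``
    (phenotype in {0,1}) or ``"quantitative"``.
    """

    table: pd.DataFrame
    trait_type: str = "binary"

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        for col in ("sample_id", "phenotype"):
            if col not in self.table.columns:
                raise SchemaError(f"phenotype table missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("phenotype table has duplicate sample ids")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def phenotype(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy()

    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "phenotype")]

    def subset(self, ids: list[str]) -> "PhenotypeTable":
        sub = self.table.set_index("sample_id").loc[list(ids)].reset_index()
        return PhenotypeTable(sub, self.trait_type)


# ---------------------------------------------------------------------------
# traw


def read_genotypes(path: str | Path, dialect: str = "traw") -> GenotypePanel:
    """Read a genotype panel from ``traw`` or ``vcf``."""
    if dialect == "traw":
        return _read_traw(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_traw(path: str | Path) -> GenotypePanel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[: len(TRAW_META_COLS)] != TRAW_META_COLS:
        raise SchemaError(
            f"{path}:1: malformed traw header, expected leading columns "
            f"{TRAW_META_COLS}, got {header[:6]}"
        )
    sample_ids = header[len(TRAW_META_COLS):]
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str, "COUNTED": str, "ALT": str})
    variants = pd.DataFrame(
        {
            "variant_id": df["SNP"],
            "chrom": df["CHR"],
            "pos": df["POS"].astype(np.int64),
            "allele_counted": df["COUNTED"],
            "allele_other": df["ALT"],
        }
    )
    dosage = df[sample_ids].to_numpy(dtype=float).T if sample_ids else np.empty((0, len(df)))
    return GenotypePanel(variants, sample_ids, dosage)


def write_genotypes(panel: GenotypePanel, path: str | Path, dialect: str = "traw") -> Path:
    """Write a panel as traw; the file reads back to an equal panel."""
    if dialect != "traw":
        raise ValueError(f"unsupported write dialect {dialect!r}")
    path = Path(path)
    meta = pd.DataFrame(
        {
            "CHR": panel.variants["chrom"],
            "SNP": panel.variants["variant_id"],
            "CM": 0,
            "POS": panel.variants["pos"],
            "COUNTED": panel.variants["allele_counted"],
            "ALT": panel.variants["allele_other"],
        }
    )
    dos = panel.dosage.T  # variants x samples
    obj = np.empty(dos.shape, dtype=object)
    nan_mask = np.isnan(dos)
    with np.errstate(invalid="ignore"):
        int_mask = ~nan_mask & (dos == np.floor(dos))
    # keep integral dosages integral in the text form
    obj[int_mask] = dos[int_mask].astype(np.int64)
    frac_mask = ~nan_mask & ~int_mask
    obj[frac_mask] = dos[frac_mask]
    obj[nan_mask] = np.nan
    out = pd.concat(
        [meta, pd.DataFrame(obj, columns=panel.sample_ids, index=meta.index)], axis=1
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def _read_vcf(path: str | Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, dosages = [], []
    n_skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append(
            {
                "variant_id": vid,
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "allele_counted": rec.ALT[0],
                "allele_other": rec.REF,
            }
        )
        gt = rec.gt_types.astype(float)  # 0=hom-ref 1=het 2=hom-alt 3=missing
        gt[gt == 3] = np.nan
        dosages.append(gt)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP VCF records", n_skipped)
    variants = pd.DataFrame(rows, columns=VARIANT_COLS)
    dosage = (
        np.asarray(dosages).T if dosages else np.empty((len(sample_ids), 0))
    )
    return GenotypePanel(variants, sample_ids, dosage)


# ---------------------------------------------------------------------------
# summary statistics


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistics TSV into the canonical frame.

    Columns in: SNP, CHR, BP, A1 (effect/counted), A2, BETA or OR, SE, P, N,
    optionally MAF.  If OR is present instead of BETA, ``beta = log(OR)``.
    Rows with non-finite beta or P are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing = [c for c in SUMSTATS_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"summary statistics missing required column(s): {missing}")
    if "BETA" in df.columns:
        beta = pd.to_numeric(df["BETA"], errors="coerce")
    elif "OR" in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.log(pd.to_numeric(df["OR"], errors="coerce"))
    else:
        raise SchemaError("summary statistics missing required column(s): ['BETA' (or 'OR')]")
    out = pd.DataFrame(
        {
            "variant_id": df["SNP"],
            "chrom": df["CHR"],
            "pos": pd.to_numeric(df["BP"], errors="coerce"),
            "effect_allele": df["A1"],
            "other_allele": df["A2"],
            "beta": beta,
            "se": pd.to_numeric(df["SE"], errors="coerce"),
            "p": pd.to_numeric(df["P"], errors="coerce"),
            "n": pd.to_numeric(df["N"], errors="coerce"),
        }
    )
    out["maf"] = pd.to_numeric(df["MAF"], errors="coerce") if "MAF" in df.columns else np.nan
    out["z"] = out["beta"] / out["se"]
    bad = ~np.isfinite(out["beta"]) | ~np.isfinite(out["p"])
    if bad.any():
        logger.info("dropped %d summary-statistics rows with non-finite beta or P", int(bad.sum()))
        out = out.loc[~bad].reset_index(drop=True)
    return out


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame(
        {
            "SNP": stats["variant_id"],
            "CHR": stats["chrom"],
            "BP": stats["pos"],
            "A1": stats["effect_allele"],
            "A2": stats["other_allele"],
            "BETA": stats["beta"],
            "SE": stats["se"],
            "P": stats["p"],
            "N": stats["n"],
        }
    )
    if "maf" in stats.columns:
        out["MAF"] = stats["maf"]
    out.to_csv(path, sep="\t", index=False)
    return path


def read_phenotypes(path: str | Path, trait_type: str = "binary") -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return PhenotypeTable(df, trait_type)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> Path:
    pheno.table.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write any tabular result as a TSV with header, columns in frame order."""
    path = Path(path)
    rows.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
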