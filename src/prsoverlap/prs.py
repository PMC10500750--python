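"""Clumping + thresholding polygenic risk scores.

SNP selection follows the classic C+T recipe: keep common SNPs (MAF >= 1%)
with association P < 0.5, exclude configured regions (e.g. +-1 Mb around a
major-effect locus), then greedy LD clumping with a +-1 Mb window at
r^2 < 0.1, indexing from the lowest P-value.  Scoring sums beta x dosage of
the effect allele over the retained SNPs, with allele flipping, removal of
strand-ambiguous pairs, and mean imputation of missing dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GenotypePanel

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SNPSelection:
    """Retained SNPs (sorted by ascending p) plus provenance counts."""

    table: pd.DataFrame  # variant_id, chrom, pos, p, beta, effect_allele, other_allele
    n_pruned: int = 0
    n_input: int = 0
    filter_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.table = self.table.sort_values(
            ["p", "chrom", "pos", "variant_id"], kind="stable"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PRSVector:
    """Per-sample polygenic score and the match report that produced it."""

    table: pd.DataFrame  # sample_id, PRS, N_SNPS_USED
    match_report: dict = field(default_factory=dict)

    @property
    def scores(self) -> np.ndarray:
        return self.table["PRS"].to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()


def filter_sumstats(
    stats: pd.DataFrame,
    maf_min: float = 0.01,
    p_max: float = 0.5,
    exclude_regions: list[tuple[str, int, int]] | None = None,
    maf_source: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the MAF / P-value / region filters to a summary-statistics frame.

    ``maf_source`` (variant_id -> MAF) overrides the stats' own MAF column;
    exclusion intervals are 1-based and inclusive on both ends.  Per-filter
    removal counts are logged and attached as ``frame.attrs['filter_counts']``.
    """
    out = stats.copy()
    counts: dict[str, int] = {}

    if "flagged" in out.columns:
        counts["flagged"] = int(out["flagged"].sum())
        out = out.loc[~out["flagged"].astype(bool)]

    if maf_source is not None:
        maf = out["variant_id"].map(maf_source)
    else:
        maf = out["maf"] if "maf" in out.columns else pd.Series(np.nan, index=out.index)
    if maf.isna().all() and maf_min > 0:
        raise ValueError("MAF filter requested but no MAF available in stats or maf_source")
    keep = maf.fillna(0.0) >= maf_min
    counts["maf"] = int((~keep).sum())
    out = out.loc[keep]

    keep = out["p"] <= p_max
    counts["pvalue"] = int((~keep).sum())
    out = out.loc[keep]

    n_region = 0
    for region in exclude_regions or []:
        chrom, start, end = region
        if start > end:
            raise ValueError(f"exclusion interval has start > end: {region}")
        hit = (out["chrom"].astype(str) == str(chrom)) & (out["pos"] >= start) & (out["pos"] <= end)
        n_region += int(hit.sum())
        out = out.loc[~hit]
    counts["region"] = n_region

    logger.info("sumstats filters removed %s", counts)
    out = out.reset_index(drop=True)
    out.attrs["filter_counts"] = counts
    return out


def clump(
    stats: pd.DataFrame,
    ld_panel: GenotypePanel,
    window_bp: int = 1_000_000,
    r2_max: float = 0.1,
) -> SNPSelection:
    """Greedy LD clumping indexed from the lowest P-value.

    Iterate variants by ascending p (ties broken by chrom, pos, variant_id);
    keep the current index SNP and remove every not-yet-kept variant on the
    same chromosome within +-window_bp whose dosage r^2 with the index is
    >= r2_max.  r^2 is the squared Pearson correlation of dosage vectors in
    ``ld_panel``.
    """
    panel_ids = ld_panel.variants["variant_id"]
    in_panel = stats["variant_id"].isin(set(panel_ids))
    n_absent = int((~in_panel).sum())
    if n_absent:
        logger.info("dropped %d stats variants absent from the LD panel", n_absent)
    work = stats.loc[in_panel].copy()
    if work.empty:
        logger.warning("clumping received no variants after filtering; empty selection")
        return SNPSelection(_selection_frame(work), n_pruned=0, n_input=len(stats))

    col_of = {v: j for j, v in enumerate(panel_ids)}
    work["_col"] = work["variant_id"].map(col_of)
    work = work.sort_values(["p", "chrom", "pos", "variant_id"], kind="stable")

    # centered dosages (missing -> column mean) for correlation computations
    G = ld_panel.dosage.astype(np.float64, copy=True)
    miss = np.isnan(G)
    if miss.any():
        col_mean = np.nanmean(G, axis=0)
        G[miss] = np.broadcast_to(col_mean, G.shape)[miss]
    G = G - G.mean(axis=0)
    norms = np.sqrt(np.einsum("nj,nj->j", G, G))
    norms[norms == 0] = np.inf  # monomorphic: r2 treated as 0

    chroms = work["chrom"].astype(str).to_numpy()
    pos = work["pos"].to_numpy()
    cols = work["_col"].to_numpy()
    order = np.arange(len(work))  # already p-sorted
    alive = np.ones(len(work), dtype=bool)
    kept_rows = []
    # pre-sort by position within chromosome for window lookups
    by_chrom: dict[str, np.ndarray] = {}
    for ch in np.unique(chroms):
        rows = np.flatnonzero(chroms == ch)
        by_chrom[ch] = rows[np.argsort(pos[rows], kind="stable")]

    for i in order:
        if not alive[i]:
            continue
        kept_rows.append(i)
        alive[i] = False
        rows = by_chrom[chroms[i]]
        lo = np.searchsorted(pos[rows], pos[i] - window_bp, side="left")
        hi = np.searchsorted(pos[rows], pos[i] + window_bp, side="right")
        cand = rows[lo:hi]
        cand = cand[alive[cand]]
        if len(cand) == 0:
            continue
        gi = G[:, cols[i]]
        r = (gi @ G[:, cols[cand]]) / (norms[cols[i]] * norms[cols[cand]])
        prune = cand[r * r >= r2_max]
        alive[prune] = False

    kept = work.iloc[sorted(kept_rows)]
    n_pruned = len(work) - len(kept)
    logger.info("clumping kept %d of %d variants", len(kept), len(work))
    return SNPSelection(_selection_frame(kept), n_pruned=n_pruned, n_input=len(stats))


def _selection_frame(stats: pd.DataFrame) -> pd.DataFrame:
    cols = ["variant_id", "chrom", "pos", "p", "beta", "effect_allele", "other_allele"]
    return stats[[c for c in cols if c in stats.columns]].reset_index(drop=True)


def select_top(selection: SNPSelection, k: int) -> SNPSelection:
    """First min(k, len) SNPs by ascending p (ties: chrom, pos, variant_id)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return SNPSelection(
        selection.table.head(min(k, len(selection.table))).copy(),
        n_pruned=selection.n_pruned,
        n_input=selection.n_input,
        filter_counts=dict(selection.filter_counts),
    )


def score(panel: GenotypePanel, selection: SNPSelection) -> PRSVector:
    """Sum of beta x effect-allele dosage over the selection's SNPs.

    If the panel counts the selection's *other* allele the dosage is
    reflected (2 - d).  Strand-ambiguous allele pairs (A/T, C/G) and SNPs
    whose alleles cannot be reconciled are dropped with logged counts.
    Missing dosages are imputed as 2 x panel allele frequency of the effect
    allele (PLINK-style mean imputation).
    """
    report = {"used": 0, "flipped": 0, "ambiguous_dropped": 0, "absent_dropped": 0,
              "mismatch_dropped": 0}
    meta = panel.variants.set_index("variant_id")
    col_of = {v: j for j, v in enumerate(panel.variants["variant_id"])}

    cols, betas, flips = [], [], []
    for row in selection.table.itertuples(index=False):
        vid = row.variant_id
        if vid not in col_of:
            report["absent_dropped"] += 1
            continue
        ea = row.effect_allele
        oa = getattr(row, "other_allele", None)
        if (ea, oa) in AMBIGUOUS_PAIRS:
            report["ambiguous_dropped"] += 1
            continue
        counted = meta.at[vid, "allele_counted"]
        other = meta.at[vid, "allele_other"]
        if ea == counted and (oa is None or oa == other):
            flip = False
        elif ea == other and (oa is None or oa == counted):
            flip = True
            report["flipped"] += 1
        else:
            report["mismatch_dropped"] += 1
            continue
        cols.append(col_of[vid])
        betas.append(row.beta)
        flips.append(flip)
    if not cols:
        raise ValueError("no usable SNPs: every selection SNP was absent or dropped")
    report["used"] = len(cols)
    dropped = {k: v for k, v in report.items() if k != "used" and v}
    if dropped:
        logger.info("scoring dropped/adjusted SNPs: %s", dropped)

    D = panel.dosage[:, cols].astype(np.float64, copy=True)
    flips_arr = np.asarray(flips, dtype=bool)
    D[:, flips_arr] = 2.0 - D[:, flips_arr]
    miss = np.isnan(D)
    n_used = np.full(panel.n_samples, len(cols))
    if miss.any():
        # effect-allele frequency in the panel (post flip reflection)
        eaf = np.nanmean(D, axis=0) / 2.0
        D[miss] = np.broadcast_to(2.0 * eaf, D.shape)[miss]
    scores = D @ np.asarray(betas)
    table = pd.DataFrame(
        {"sample_id": panel.sample_ids, "PRS": scores, "N_SNPS_USED": n_used}
    )
    return PRSVector(table, report)
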