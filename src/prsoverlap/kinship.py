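"""Cross-cohort relatedness via IBS counts and method-of-moments IBD (PI_HAT).

Implements the classic moments estimator: observed counts of loci sharing
0/1/2 alleles identical by state are compared with their Hardy-Weinberg
expectations under IBD states 0/1/2, solved for P(IBD=k), clamped to [0, 1]
and renormalized.  PI_HAT = P(IBD=2) + 0.5 P(IBD=1): 1 for duplicates,
about 0.5 for first-degree relatives, about 0 for unrelated pairs.

Pairwise IBS counting across two panels is done with three indicator-matrix
products, so all-pairs runs stay in seconds at desk scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .formats import GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

MIN_INFORMATIVE_LOCI = 100


def ibs_counts(g1: np.ndarray, g2: np.ndarray) -> tuple[int, int, int]:
    """Counts of loci with 0/1/2 alleles shared identical by state.

    IBS at a locus is 2 - |d1 - d2| for dosages in {0, 1, 2}; loci missing in
    either sample are excluded.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError(f"length mismatch: {g1.shape} vs {g2.shape}")
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    ibs = 2.0 - np.abs(g1[ok] - g2[ok])
    return int((ibs == 0).sum()), int((ibs == 1).sum()), int((ibs == 2).sum())


def _expected_ibs_given_ibd(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """Summed-over-loci expected IBS-state probabilities under HWE.

    Returns (e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1); under IBD=2 every
    locus is IBS=2.
    """
    q = 1.0 - p
    e0_ibd0 = float(np.sum(2.0 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4.0 * p**3 * q + 4.0 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4.0 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2.0 * p * q))
    e2_ibd1 = float(np.sum(1.0 - 2.0 * p * q))
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def _moments_ibd(
    ibs0: np.ndarray, ibs1: np.ndarray, ibs2: np.ndarray, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve observed IBS counts for P(IBD=0/1/2), clamp and renormalize."""
    m = ibs0 + ibs1 + ibs2
    e0_0, e1_0, e2_0, e1_1, e2_1 = _expected_ibs_given_ibd(freqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        n0 = ibs0 / (e0_0 / len(freqs))
        n1 = (ibs1 - n0 * (e1_0 / len(freqs))) / (e1_1 / len(freqs))
        n2 = (ibs2 - n0 * (e2_0 / len(freqs)) - n1 * (e2_1 / len(freqs))) / 1.0
    p0, p1, p2 = n0 / m, n1 / m, n2 / m
    p0 = np.clip(p0, 0.0, 1.0)
    p1 = np.clip(p1, 0.0, 1.0)
    p2 = np.clip(p2, 0.0, 1.0)
    total = p0 + p1 + p2
    total[total == 0] = 1.0
    return p0 / total, p1 / total, p2 / total


def _indicator_products(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, ...]:
    """All-pairs IBS counts between rows of A and rows of B.

    Missing dosages participate in no category, so per-pair loci counts vary.
    """
    # indicator stacks per dosage category, float32 keeps the GEMMs fast
    Ak = [np.ascontiguousarray((A == k), dtype=np.float32) for k in (0, 1, 2)]
    Bk = [np.ascontiguousarray((B == k).T, dtype=np.float32) for k in (0, 1, 2)]
    ibs0 = Ak[0] @ Bk[2] + Ak[2] @ Bk[0]
    ibs2 = Ak[0] @ Bk[0] + Ak[1] @ Bk[1] + Ak[2] @ Bk[2]
    okA = (~np.isnan(A)).astype(np.float32)
    okB = (~np.isnan(B)).astype(np.float32).T
    n_loci = okA @ okB
    ibs1 = n_loci - ibs0 - ibs2
    return ibs0, ibs1, ibs2, n_loci


def estimate_pi_hat(
    panel_a: GenotypePanel,
    panel_b: GenotypePanel,
    maf_min: float = 0.01,
    external_freqs: pd.Series | None = None,
) -> pd.DataFrame:
    """All cross-panel pairwise PI_HAT estimates.

    Shared variants are filtered to MAF >= ``maf_min``; allele frequencies
    come from the pooled pair of panels unless ``external_freqs``
    (variant_id -> counted-allele frequency) is given.  Returns a frame with
    columns ID1 ID2 IBS0 IBS1 IBS2 P0 P1 P2 PI_HAT NLOCI UNSTABLE.
    """
    ids_a = panel_a.variants["variant_id"]
    shared = ids_a[ids_a.isin(set(panel_b.variants["variant_id"]))].tolist()
    if not shared:
        raise ValueError("panels share no variants")
    sub_a = panel_a.subset_variants(shared)
    sub_b = panel_b.subset_variants(shared)

    if external_freqs is not None:
        freq = sub_a.variants["variant_id"].map(external_freqs).to_numpy(dtype=float)
    else:
        na, nb = sub_a.n_samples, sub_b.n_samples
        freq = (na * sub_a.allele_freq() + nb * sub_b.allele_freq()) / (na + nb)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError(f"no shared variants pass MAF >= {maf_min}")
    kept_ids = sub_a.variants.loc[keep, "variant_id"].tolist()
    sub_a = sub_a.subset_variants(kept_ids)
    sub_b = sub_b.subset_variants(kept_ids)
    freq = freq[keep]

    ibs0, ibs1, ibs2, n_loci = _indicator_products(sub_a.dosage, sub_b.dosage)
    p0, p1, p2 = _moments_ibd(
        ibs0.astype(np.float64), ibs1.astype(np.float64), ibs2.astype(np.float64), freq
    )
    pi_hat = p2 + 0.5 * p1

    na, nb = sub_a.n_samples, sub_b.n_samples
    id1 = np.repeat(sub_a.sample_ids, nb)
    id2 = np.tile(sub_b.sample_ids, na)
    out = pd.DataFrame(
        {
            "ID1": id1,
            "ID2": id2,
            "IBS0": ibs0.ravel().astype(np.int64),
            "IBS1": ibs1.ravel().astype(np.int64),
            "IBS2": ibs2.ravel().astype(np.int64),
            "P0": p0.ravel(),
            "P1": p1.ravel(),
            "P2": p2.ravel(),
            "PI_HAT": pi_hat.ravel(),
            "NLOCI": n_loci.ravel().astype(np.int64),
        }
    )
    out["UNSTABLE"] = out["NLOCI"] < MIN_INFORMATIVE_LOCI
    n_unstable = int(out["UNSTABLE"].sum())
    if n_unstable:
        logger.warning(
            "%d pairs share < %d informative loci; their estimates are unstable",
            n_unstable,
            MIN_INFORMATIVE_LOCI,
        )
    return out


def prune_overlap(
    test_panel: GenotypePanel,
    test_pheno: PhenotypeTable,
    discovery_panel: GenotypePanel,
    pi_hat_cutoff: float,
    maf_min: float = 0.01,
    kinship: pd.DataFrame | None = None,
) -> tuple[GenotypePanel, PhenotypeTable, pd.DataFrame]:
    """Remove test subjects related to any discovery subject at PI_HAT >= cutoff.

    Returns the pruned cohort plus a report of removed IDs with their
    best-matching discovery ID and PI_HAT.  ``kinship`` may supply a
    precomputed table (ID1 = test, ID2 = discovery).
    """
    if not 0.0 < pi_hat_cutoff <= 1.0:
        raise ValueError(f"pi_hat_cutoff must be in (0, 1], got {pi_hat_cutoff}")
    if kinship is None:
        kinship = estimate_pi_hat(test_panel, discovery_panel, maf_min=maf_min)
    best = (
        kinship.sort_values("PI_HAT", ascending=False)
        .drop_duplicates("ID1")
        .set_index("ID1")
    )
    removed = best.loc[best["PI_HAT"] >= pi_hat_cutoff]
    report = pd.DataFrame(
        {
            "removed_id": removed.index,
            "best_match_id": removed["ID2"].to_numpy(),
            "pi_hat": removed["PI_HAT"].to_numpy(),
        }
    ).reset_index(drop=True)
    keep_ids = [s for s in test_panel.sample_ids if s not in set(report["removed_id"])]
    if not keep_ids:
        raise ValueError(
            f"pruning at PI_HAT >= {pi_hat_cutoff} removed every test subject; "
            "raise the cutoff"
        )
    logger.info("pruned %d of %d test subjects", len(report), test_panel.n_samples)
    return test_panel.subset_samples(keep_ids), test_pheno.subset(keep_ids), report
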