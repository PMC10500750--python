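"""Discovery-phase association: per-SNP regressions and principal components.

Binary traits use per-variant logistic regression (Wald tests), quantitative
traits ordinary least squares.  Both are vectorized across variants: the
covariate block of each per-variant design matrix is shared, so the normal
equations are assembled for all variants at once and solved as a batch.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 25


def _design_covariates(pheno: PhenotypeTable, covariate_names: list[str]) -> np.ndarray:
    """Intercept + named covariates; errors on collinear columns."""
    cols = [np.ones(len(pheno.table))]
    for name in covariate_names:
        if name not in pheno.table.columns:
            raise KeyError(f"covariate {name!r} not in phenotype table")
        cols.append(pheno.table[name].to_numpy(dtype=float))
    U = np.column_stack(cols)
    rank = np.linalg.matrix_rank(U)
    if rank < U.shape[1]:
        # identify offenders by dropping columns one at a time
        bad = [
            covariate_names[j - 1]
            for j in range(1, U.shape[1])
            if np.linalg.matrix_rank(np.delete(U, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    return U


def _prepare_dosage(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-impute missing dosages; flag all-missing and monomorphic variants."""
    G = panel.dosage.astype(np.float64, copy=True)
    miss = np.isnan(G)
    n_missing_cells = int(miss.sum())
    all_missing = miss.all(axis=0)
    if n_missing_cells:
        logger.info("mean-imputed %d missing dosage cells for association", n_missing_cells)
        col_mean = np.nanmean(np.where(all_missing[None, :], 0.0, G), axis=0)
        col_mean[all_missing] = 0.0
        G[miss] = np.broadcast_to(col_mean, G.shape)[miss]
    with np.errstate(invalid="ignore"):
        monomorphic = np.nanstd(G, axis=0) == 0
    return G, all_missing, monomorphic | all_missing


def run_gwas(
    panel: GenotypePanel,
    pheno: PhenotypeTable,
    covariate_names: list[str] | None = None,
    trait_type: str = "binary",
) -> pd.DataFrame:
    """Per-variant association scan: phenotype ~ dosage + covariates.

    Returns the canonical summary-statistics frame (variant_id, chrom, pos,
    effect_allele = the panel's counted allele, other_allele, beta, se, z, p,
    n, maf) plus a boolean ``flagged`` column marking monomorphic or
    non-converged fits (reported with beta = 0, p = 1 and excluded
    downstream).
    """
    if pheno.sample_ids != panel.sample_ids:
        pheno = pheno.subset(panel.sample_ids)
    covariate_names = list(covariate_names or [])
    y = pheno.phenotype.astype(np.float64)
    if trait_type == "binary":
        classes = np.unique(y)
        if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
            raise ValueError("binary GWAS needs phenotype coded 0/1 with both classes present")
    U = _design_covariates(pheno, covariate_names)
    G, all_missing, flagged = _prepare_dosage(panel)

    if trait_type == "binary":
        beta, se, converged = _logistic_scan(y, U, G, ~flagged)
    elif trait_type == "quantitative":
        beta, se, converged = _linear_scan(y, U, G, ~flagged)
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")

    flagged = flagged | ~converged
    beta = np.where(flagged, 0.0, beta)
    se = np.where(flagged, np.nan, se)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(flagged, 0.0, beta / se)
    p = np.where(flagged, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    freq = np.nanmean(panel.dosage, axis=0) / 2.0
    freq[all_missing] = np.nan
    out = panel.variants[["variant_id", "chrom", "pos"]].copy()
    out["effect_allele"] = panel.variants["allele_counted"]
    out["other_allele"] = panel.variants["allele_other"]
    out["beta"] = beta
    out["se"] = se
    out["z"] = z
    out["p"] = p
    out["n"] = panel.n_samples
    out["maf"] = np.minimum(freq, 1.0 - freq)
    out["flagged"] = flagged
    n_flag = int(flagged.sum())
    if n_flag:
        logger.info("flagged %d variants (monomorphic / all-missing / non-converged)", n_flag)
    return out


def _linear_scan(
    y: np.ndarray, U: np.ndarray, G: np.ndarray, fit_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-variant OLS slope via Frisch-Waugh residualization."""
    n, m = G.shape
    Q, _ = np.linalg.qr(U)
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)
    gg = np.einsum("nj,nj->j", G_res, G_res)
    gy = G_res.T @ y_res
    ok = fit_mask & (gg > 0)
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    dof = n - U.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[ok] = gy[ok] / gg[ok]
        rss = np.einsum("n,n->", y_res, y_res) - beta[ok] ** 2 * gg[ok]
        se[ok] = np.sqrt(np.maximum(rss, 0.0) / dof / gg[ok])
    return beta, se, np.ones(m, dtype=bool)


def _logistic_scan(
    y: np.ndarray, U: np.ndarray, G: np.ndarray, fit_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for phenotype ~ intercept + covariates + dosage.

    One Newton system of size (c+2) per variant per iteration, assembled with
    einsum across all variants simultaneously.  Convergence: max coefficient
    change < 1e-8 within 25 iterations (separation leaves a variant flagged
    non-converged).
    """
    n, m = G.shape
    c1 = U.shape[1]
    p_dim = c1 + 1
    idx = np.flatnonzero(fit_mask)
    Gf = G[:, idx]
    mf = len(idx)

    # warm start from the covariate-only fit (shared across variants)
    from statsmodels.api import GLM, families

    null = GLM(y, U, family=families.Binomial()).fit()
    coef = np.zeros((mf, p_dim))
    coef[:, :c1] = null.params

    converged_f = np.zeros(mf, dtype=bool)
    active = np.ones(mf, dtype=bool)
    eps = 1e-10
    for _ in range(IRLS_MAX_ITER):
        if not active.any():
            break
        a = np.flatnonzero(active)
        Ga = Gf[:, a]
        eta = U @ coef[a, :c1].T + Ga * coef[a, c1]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), eps, None)
        z = eta + (y[:, None] - mu) / w

        A11 = np.einsum("ni,nj,nk->jik", U, w, U, optimize=True)
        A12 = np.einsum("ni,nj,nj->ji", U, w, Ga, optimize=True)
        A22 = np.einsum("nj,nj,nj->j", Ga, w, Ga)
        b1 = np.einsum("ni,nj,nj->ji", U, w, z, optimize=True)
        b2 = np.einsum("nj,nj,nj->j", Ga, w, z)

        A = np.empty((len(a), p_dim, p_dim))
        A[:, :c1, :c1] = A11
        A[:, :c1, c1] = A12
        A[:, c1, :c1] = A12
        A[:, c1, c1] = A22
        b = np.concatenate([b1, b2[:, None]], axis=1)
        try:
            new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # fall back to pseudo-inverse for singular systems
            new = np.einsum("jik,jk->ji", np.linalg.pinv(A), b)
        bad = ~np.isfinite(new).all(axis=1)
        new[bad] = coef[a[bad]]
        delta = np.abs(new - coef[a]).max(axis=1)
        coef[a] = new
        done = (delta < IRLS_TOL) & ~bad
        converged_f[a[done]] = True
        active[a[done]] = False
        active[a[bad]] = False

    # Wald SEs from the observed information at the final coefficients
    eta = U @ coef[:, :c1].T + Gf * coef[:, c1]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), eps, None)
    A11 = np.einsum("ni,nj,nk->jik", U, w, U, optimize=True)
    A12 = np.einsum("ni,nj,nj->ji", U, w, Gf, optimize=True)
    A22 = np.einsum("nj,nj,nj->j", Gf, w, Gf)
    A = np.empty((mf, p_dim, p_dim))
    A[:, :c1, :c1] = A11
    A[:, :c1, c1] = A12
    A[:, c1, :c1] = A12
    A[:, c1, c1] = A22
    try:
        cov_last = np.linalg.inv(A)[:, c1, c1]
    except np.linalg.LinAlgError:
        cov_last = np.linalg.pinv(A)[:, c1, c1]

    beta = np.zeros(m)
    se = np.full(m, np.nan)
    converged = np.zeros(m, dtype=bool)
    beta[idx] = coef[:, c1]
    with np.errstate(invalid="ignore"):
        se[idx] = np.sqrt(np.where(cov_last > 0, cov_last, np.nan))
    converged[idx] = converged_f & np.isfinite(se[idx])
    return beta, se, converged


def compute_pcs(panel: GenotypePanel, k: int, seed: int = 0) -> np.ndarray:
    """Leading principal-component scores of the standardized dosage matrix.

    Orthonormal columns; deterministic sign convention (the largest-magnitude
    variant loading of each component is positive).  Computed by randomized
    SVD with a fixed seed so runs are reproducible.
    """
    if k > min(panel.n_samples, panel.n_variants):
        raise ValueError(
            f"k={k} exceeds min(n_samples, n_variants) = "
            f"{min(panel.n_samples, panel.n_variants)}"
        )
    if k == 0:
        return np.empty((panel.n_samples, 0))
    from sklearn.utils.extmath import randomized_svd

    G = panel.dosage.astype(np.float64, copy=True)
    miss = np.isnan(G)
    if miss.any():
        col_mean = np.nanmean(G, axis=0)
        G[miss] = np.broadcast_to(col_mean, G.shape)[miss]
    freq = G.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * freq * (1.0 - freq))
    sd[sd == 0] = 1.0
    X = (G - 2.0 * freq) / sd
    U, S, Vt = randomized_svd(X, n_components=k, n_iter=7, random_state=seed)
    sign = np.sign(Vt[np.arange(k), np.abs(Vt).argmax(axis=1)])
    sign[sign == 0] = 1.0
    return U * sign
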