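"""Model fitting and the ΔAUC / ΔR² machinery.

Three nested regression models are compared on the test cohort:

* Model I:   phenotype ~ PRS only
* Model II:  phenotype ~ covariates + leading PCs (no PRS)
* Model III: Model II + PRS

The additive gain of the PRS term is ΔAUC = AUC(III) − AUC(II) with DeLong's
paired test for binary traits, and Δadjusted-R² with the extra-sum-of-squares
F test for quantitative traits.  Nagelkerke's pseudo-R² (intercept-only
baseline) is the binary R² analog.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import PhenotypeTable
from .prs import PRSVector

logger = logging.getLogger(__name__)

DEFAULT_N_PCS = 20


@dataclass
class ModelSpec:
    """Which model to fit and with what ingredients."""

    model: str  # "I", "II" or "III"
    covariate_names: list[str] = field(default_factory=list)
    n_pcs: int = DEFAULT_N_PCS
    trait_type: str = "binary"

    def __post_init__(self) -> None:
        if self.model not in ("I", "II", "III"):
            raise ValueError(f"model must be I, II or III, got {self.model!r}")

    @property
    def include_prs(self) -> bool:
        return self.model in ("I", "III")


@dataclass
class ModelFit:
    params: pd.Series
    fitted: np.ndarray  # linear predictor (risk score) per sample
    n: int
    converged: bool
    trait_type: str
    llf: float | None = None  # binary
    rss: float | None = None  # quantitative
    df_model: int = 0  # regressors excluding intercept
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class DeltaMetrics:
    """Headline quantities: the additive gain of the PRS term over Model II."""

    auc_II: float | None = None
    auc_III: float | None = None
    delta_auc: float | None = None
    delong_p: float | None = None
    r2_II: float = np.nan
    r2_III: float = np.nan
    delta_r2: float = np.nan
    r2_p: float = np.nan

    def to_dict(self) -> dict:
        return {
            "auc_II": self.auc_II,
            "auc_III": self.auc_III,
            "delta_auc": self.delta_auc,
            "delong_p": self.delong_p,
            "r2_II": self.r2_II,
            "r2_III": self.r2_III,
            "delta_r2": self.delta_r2,
            "r2_p": self.r2_p,
        }


# ---------------------------------------------------------------------------
# design assembly and fitting


def _assemble_design(
    pheno: PhenotypeTable,
    prs: PRSVector | np.ndarray | None,
    pcs: np.ndarray | None,
    spec: ModelSpec,
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Inner-join inputs on sample ID and build the design frame.

    Returns (y, X frame without intercept, dropped constant columns).
    """
    tab = pheno.table
    if isinstance(prs, PRSVector):
        joined = tab.merge(
            prs.table[["sample_id", "PRS"]], on="sample_id", how="inner", validate="1:1"
        )
        if len(joined) < len(tab):
            logger.info("dropped %d samples without PRS", len(tab) - len(joined))
        tab = joined
        prs_values = tab["PRS"].to_numpy()
    elif prs is not None:
        prs_values = np.asarray(prs, dtype=float)
        if len(prs_values) != len(tab):
            raise ValueError("PRS array length does not match phenotype table")
    else:
        prs_values = None

    y = tab["phenotype"].to_numpy(dtype=float)
    X = pd.DataFrame(index=tab.index)
    if spec.model in ("II", "III"):
        for name in spec.covariate_names:
            if name not in tab.columns:
                raise KeyError(f"covariate {name!r} not in phenotype table")
            X[name] = tab[name].to_numpy(dtype=float)
        if spec.n_pcs and pcs is not None:
            k = min(spec.n_pcs, pcs.shape[1])
            for j in range(k):
                X[f"PC{j + 1}"] = pcs[tab.index.to_numpy(), j] if len(pcs) != len(tab) else pcs[:, j]
    if spec.include_prs:
        if prs_values is None:
            raise ValueError(f"Model {spec.model} needs a PRS")
        X["PRS"] = prs_values

    dropped = []
    for col in list(X.columns):
        if np.nanstd(X[col].to_numpy()) == 0:
            if col == "PRS":
                logger.warning("PRS column is constant; dropped from Model %s", spec.model)
                dropped.append(col)
                X = X.drop(columns=[col])
            else:
                raise ValueError(f"constant covariate column {col!r}")
    return y, X, dropped


def fit_model(
    pheno: PhenotypeTable,
    prs: PRSVector | np.ndarray | None,
    pcs: np.ndarray | None,
    spec: ModelSpec,
) -> ModelFit:
    """Fit one of Models I/II/III; logistic IRLS (tol 1e-8) or least squares."""
    y, X, dropped = _assemble_design(pheno, prs, pcs, spec)
    names = ["const"] + list(X.columns)
    design = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = [
            names[j]
            for j in range(1, design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"collinear design; offending columns: {bad}")

    import statsmodels.api as sm

    if spec.trait_type == "binary":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("binary model needs both classes present")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
        fitted = design @ res.params
        return ModelFit(
            params=pd.Series(res.params, index=names),
            fitted=fitted,
            n=len(y),
            converged=bool(res.converged),
            trait_type="binary",
            llf=float(res.llf),
            df_model=design.shape[1] - 1,
            dropped_columns=dropped,
        )
    res = sm.OLS(y, design).fit()
    return ModelFit(
        params=pd.Series(res.params, index=names),
        fitted=design @ res.params,
        n=len(y),
        converged=True,
        trait_type="quantitative",
        rss=float(res.ssr),
        df_model=design.shape[1] - 1,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# AUC and DeLong


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus its structural components V10 (cases) and V01 (controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    a = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return a, v10, v01


def delong_delta_auc(
    scores_II: np.ndarray, scores_III: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """ΔAUC of two paired score vectors with DeLong's two-sided test.

    Degenerate case (zero variance of the AUC difference, e.g. identical
    score vectors): returns (delta, 1.0) by convention.
    """
    scores_II = np.asarray(scores_II, dtype=float)
    scores_III = np.asarray(scores_III, dtype=float)
    labels = np.asarray(labels)
    if scores_II.shape != scores_III.shape or scores_II.shape != labels.shape:
        raise ValueError("paired scores and labels must share one shape")
    a2, v10_2, v01_2 = _delong_components(scores_II, labels)
    a3, v10_3, v01_3 = _delong_components(scores_III, labels)
    delta = a3 - a2
    m, n = len(v10_2), len(v01_2)
    s10 = np.cov(np.stack([v10_3, v10_2]))
    s01 = np.cov(np.stack([v01_3, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if not np.isfinite(var) or var <= 0:
        logger.info("DeLong variance degenerate; returning p = 1 by convention")
        return float(delta), 1.0
    z = delta / np.sqrt(var)
    return float(delta), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# R² measures


def nagelkerke_r2(fit: ModelFit, null_fit: ModelFit) -> float:
    """Nagelkerke pseudo-R² of ``fit`` against an intercept-only null.

    R² = (1 − exp((2/n)(LL0 − LL1))) / (1 − exp((2/n) LL0)).
    """
    if fit.llf is None or null_fit.llf is None:
        raise ValueError("nagelkerke_r2 needs binary (log-likelihood) fits")
    if fit.n != null_fit.n:
        raise ValueError("fits are on different samples")
    ll1, ll0 = fit.llf, null_fit.llf
    if ll1 < ll0 - 1e-6:
        raise ValueError(
            f"nesting violated: full-model log-likelihood {ll1:.6f} below null {ll0:.6f}"
        )
    n = fit.n
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    max_r2 = 1.0 - np.exp((2.0 / n) * ll0)
    return float(cox_snell / max_r2)


def adjusted_r2(fit: ModelFit, tss: float) -> float:
    if fit.rss is None:
        raise ValueError("adjusted_r2 needs a quantitative fit")
    n, p = fit.n, fit.df_model
    return 1.0 - (fit.rss / (n - p - 1)) / (tss / (n - 1))


def extra_ss_test(fit_II: ModelFit, fit_III: ModelFit, tss: float) -> tuple[float, float, float]:
    """Extra-sum-of-squares F test of Model III over nested Model II.

    Returns (Δadjusted-R², F, p).
    """
    if fit_II.rss is None or fit_III.rss is None:
        raise ValueError("extra_ss_test needs quantitative fits")
    if fit_II.n != fit_III.n:
        raise ValueError("fits are on different samples")
    ddf = fit_III.df_model - fit_II.df_model
    if ddf < 0:
        raise ValueError("Model II is not nested in Model III (more regressors)")
    delta_adj = adjusted_r2(fit_III, tss) - adjusted_r2(fit_II, tss)
    if ddf == 0:
        return delta_adj, 0.0, 1.0
    dfe = fit_III.n - fit_III.df_model - 1
    num = (fit_II.rss - fit_III.rss) / ddf
    den = fit_III.rss / dfe
    if den <= 0 or num <= 0:
        return delta_adj, 0.0, 1.0
    F = num / den
    p = float(stats.f.sf(F, ddf, dfe))
    return delta_adj, float(F), p


# ---------------------------------------------------------------------------
# cross-validation


def stratified_kfold(
    pheno: PhenotypeTable,
    strat_columns: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """Covariate-balanced k-fold splits (discovery = complement of test fold).

    Strata are the cross-classification of the given columns (continuous
    columns binned into quintiles); within each stratum samples are dealt
    round-robin after shuffling, so fold counts per stratum differ by at most
    one.  Strata smaller than k are merged (with a warning) into one pooled
    remainder stratum.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    tab = pheno.table
    strat_columns = list(strat_columns or ["phenotype"])
    keys = []
    for col in strat_columns:
        x = tab[col]
        if x.nunique() > 10 and pd.api.types.is_numeric_dtype(x):
            keys.append(pd.qcut(x, 5, labels=False, duplicates="drop").astype(str))
        else:
            keys.append(x.astype(str))
    stratum = keys[0]
    for extra in keys[1:]:
        stratum = stratum + "|" + extra

    sizes = stratum.value_counts()
    small = sizes.index[sizes < k]
    if len(small):
        logger.warning("merged %d strata smaller than k=%d into a pooled stratum", len(small), k)
        stratum = stratum.where(~stratum.isin(set(small)), other="__merged__")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fold_of = np.empty(len(tab), dtype=int)
    start = rng.integers(0, k)
    for _, idx in tab.groupby(stratum.to_numpy()).groups.items():
        idx = np.asarray(list(idx))
        rng.shuffle(idx)
        fold_of[idx] = (np.arange(len(idx)) + start) % k
        start = int((start + len(idx)) % k)

    ids = tab["sample_id"].to_numpy()
    folds = []
    for f in range(k):
        test_ids = ids[fold_of == f].tolist()
        disc_ids = ids[fold_of != f].tolist()
        folds.append((disc_ids, test_ids))
    return folds


# ---------------------------------------------------------------------------


def evaluate(
    prs: PRSVector | np.ndarray,
    pheno: PhenotypeTable,
    pcs: np.ndarray | None,
    trait_type: str = "binary",
    covariate_names: list[str] | None = None,
    n_pcs: int = DEFAULT_N_PCS,
) -> DeltaMetrics:
    """Fit Models II and III and return the PRS term's additive gain.

    Binary: ΔAUC with DeLong p, ΔNagelkerke-R².  Quantitative: Δadjusted-R²
    with the extra-sum-of-squares p (plain R²s also populate r2_II/r2_III).
    A constant PRS makes Model III collapse to Model II, so all deltas are 0.
    """
    covariate_names = list(covariate_names or [])
    spec_II = ModelSpec("II", covariate_names, n_pcs, trait_type)
    spec_III = ModelSpec("III", covariate_names, n_pcs, trait_type)
    fit_II = fit_model(pheno, prs, pcs, spec_II)
    fit_III = fit_model(pheno, prs, pcs, spec_III)

    if trait_type == "binary":
        y = pheno.table["phenotype"].to_numpy()
        if isinstance(prs, PRSVector):
            # evaluation happens on the joined sample set
            joined = pheno.table.merge(prs.table[["sample_id", "PRS"]], on="sample_id")
            y = joined["phenotype"].to_numpy()
        auc_II = auc(fit_II.fitted, y)
        auc_III = auc(fit_III.fitted, y)
        if fit_III.dropped_columns:
            delta, p = 0.0, 1.0
            auc_III = auc_II
        else:
            delta, p = delong_delta_auc(fit_II.fitted, fit_III.fitted, y)
        null_fit = fit_model(pheno, prs, None, ModelSpec("II", [], 0, "binary"))
        r2_II = nagelkerke_r2(fit_II, null_fit)
        r2_III = nagelkerke_r2(fit_III, null_fit) if not fit_III.dropped_columns else r2_II
        return DeltaMetrics(
            auc_II=auc_II,
            auc_III=auc_III,
            delta_auc=delta,
            delong_p=p,
            r2_II=r2_II,
            r2_III=r2_III,
            delta_r2=r2_III - r2_II,
            r2_p=p,
        )

    y = pheno.table["phenotype"].to_numpy(dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    if fit_III.dropped_columns:
        r2 = adjusted_r2(fit_II, tss)
        return DeltaMetrics(r2_II=r2, r2_III=r2, delta_r2=0.0, r2_p=1.0)
    delta_adj, _F, p = extra_ss_test(fit_II, fit_III, tss)
    return DeltaMetrics(
        r2_II=adjusted_r2(fit_II, tss),
        r2_III=adjusted_r2(fit_III, tss),
        delta_r2=delta_adj,
        r2_p=p,
    )
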