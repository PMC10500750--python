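"""The study designs: contamination, scale, SNP-count, power and case:control.

Each experiment orchestrates the full stack — simulate a cohort pool, run the
discovery GWAS, build a clumping + thresholding PRS, score an independent (or
deliberately contaminated) test set, and measure the PRS term's additive gain
(ΔAUC / ΔR²) — over a grid of one design axis, with replicate summaries
(mean ± sd) per grid point.

Replicate seeds derive from the master seed by a counter-based scheme
(SeedSequence spawn keys), recorded per cell so any single cell can be
re-run in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evalmetrics, kinship
from .assoc import compute_pcs, run_gwas
from .formats import GenotypePanel, PhenotypeTable
from .prs import SNPSelection, clump, filter_sumstats, score, select_top
from .simulate import SimulationConfig, build_cohorts, inject_overlap, simulate_cohort

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps -log10(P) finite in grids

#: experiment-scale covariate architecture: age and sex are nuisance, the
#: apoe4 analog carries real liability risk so the single-covariate
#: reference model is informative.
EXPERIMENT_COVARIATES = {"age": 0.1, "sex": 0.1, "apoe4": 0.5}


@dataclass
class ExperimentGrid:
    """Per-cell ΔAUC/ΔR² results over one design axis plus summaries."""

    design: str
    axis: str
    cells: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        agg = (
            self.cells.groupby("point")
            .agg(
                mean_delta_auc=("delta_auc", "mean"),
                sd_delta_auc=("delta_auc", "std"),
                mean_delta_r2=("delta_r2", "mean"),
                sd_delta_r2=("delta_r2", "std"),
                mean_neglog_p=("neglog_p", "mean"),
                n_replicates=("replicate", "count"),
            )
            .reset_index()
        )
        return agg.rename(columns={"point": self.axis})


def _cell_seed(master_seed: int, *key: int) -> int:
    """Counter-based per-cell seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _neglog(p: float) -> float:
    return float(-np.log10(max(p, P_FLOOR)))


def build_prs(
    disc_panel: GenotypePanel,
    disc_pheno: PhenotypeTable,
    covariate_names: list[str],
    trait_type: str,
    maf_min: float = 0.01,
    p_max: float = 0.5,
    window_bp: int = 1_000_000,
    r2_max: float = 0.1,
    exclude_regions: list[tuple[str, int, int]] | None = None,
) -> SNPSelection:
    """Discovery GWAS followed by the C+T SNP selection."""
    stats = run_gwas(disc_panel, disc_pheno, covariate_names, trait_type)
    filt = filter_sumstats(stats, maf_min=maf_min, p_max=p_max, exclude_regions=exclude_regions)
    return clump(filt, disc_panel, window_bp=window_bp, r2_max=r2_max)


def _evaluate_cell(
    selection: SNPSelection,
    test_panel: GenotypePanel,
    test_pheno: PhenotypeTable,
    covariate_names: list[str],
    trait_type: str,
    n_pcs: int,
    pc_seed: int = 0,
) -> evalmetrics.DeltaMetrics:
    pcs = compute_pcs(test_panel, min(n_pcs, test_panel.n_samples - 1), seed=pc_seed)
    prs = score(test_panel, selection)
    return evalmetrics.evaluate(
        prs, test_pheno, pcs, trait_type, covariate_names, n_pcs=n_pcs
    )


def _metrics_row(dm: evalmetrics.DeltaMetrics, trait_type: str) -> dict:
    if trait_type == "binary":
        return {
            "delta_auc": dm.delta_auc,
            "delta_r2": dm.delta_r2,
            "p": dm.delong_p,
            "neglog_p": _neglog(dm.delong_p),
        }
    return {
        "delta_auc": np.nan,
        "delta_r2": dm.delta_r2,
        "p": dm.r2_p,
        "neglog_p": _neglog(dm.r2_p),
    }


def _config_for(config: SimulationConfig, n_samples: int, seed: int) -> SimulationConfig:
    return replace(config, n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------------
# 1. contamination sweep (discovery subjects replace test subjects, 0..100%)


def contamination_experiment(
    config: SimulationConfig,
    n_discovery: int = 3000,
    n_test: int = 800,
    fractions: np.ndarray | None = None,
    replicates: int = 20,
    seed: int = 0,
    n_pcs: int = 20,
    reference_covariate: str = "apoe4",
) -> ExperimentGrid:
    """Sweep the fraction of test subjects copied from the discovery set.

    Per replicate: simulate a pool, split into discovery and an initially
    independent test set, fit the discovery GWAS and C+T selection once, then
    for each fraction replace that share of test subjects with discovery
    subjects and re-evaluate.  A single-covariate reference model (the apoe4
    analog alone added to Model II) is evaluated per fraction as a stability
    control.
    """
    fractions = np.round(np.arange(0.0, 1.01, 0.1), 2) if fractions is None else np.asarray(fractions)
    rows = []
    for rep in range(replicates):
        cseed = _cell_seed(seed, 0, rep)
        cfg = _config_for(config, n_discovery + n_test, cseed)
        panel, pheno, _ = simulate_cohort(cfg, "binary")
        pair = build_cohorts(panel, pheno, n_discovery, n_test, 0.0, seed=cseed)
        covars = pair.discovery_pheno.covariate_names()
        selection = build_prs(pair.discovery_panel, pair.discovery_pheno, covars, "binary")
        for fi, frac in enumerate(fractions):
            t_panel, t_pheno, injected = inject_overlap(
                pair.test_panel,
                pair.test_pheno,
                pair.discovery_panel,
                pair.discovery_pheno,
                float(frac),
                seed=_cell_seed(seed, 1, rep, fi),
            )
            dm = _evaluate_cell(selection, t_panel, t_pheno, covars, "binary", n_pcs, pc_seed=cseed)
            row = {"point": float(frac), "replicate": rep, "seed": cseed,
                   "n_injected": len(injected), **_metrics_row(dm, "binary")}
            if reference_covariate in covars:
                ref_covars = [c for c in covars if c != reference_covariate]
                ref = evalmetrics.evaluate(
                    t_pheno.table[reference_covariate].to_numpy(dtype=float),
                    t_pheno,
                    compute_pcs(t_panel, min(n_pcs, t_panel.n_samples - 1), seed=cseed),
                    "binary",
                    ref_covars,
                    n_pcs=n_pcs,
                )
                row["ref_delta_auc"] = ref.delta_auc
            rows.append(row)
    return ExperimentGrid("contamination", "overlap_fraction", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# 2. prune-repair (contaminate, then deduplicate by PI_HAT)


def prune_repair_experiment(
    config: SimulationConfig,
    n_discovery: int = 3000,
    n_test: int = 800,
    contamination: float = 0.3,
    pi_hat_cutoff: float = 0.9,
    replicates: int = 10,
    seed: int = 0,
    n_pcs: int = 20,
    kinship_loci: int = 2000,
) -> pd.DataFrame:
    """Three arms per replicate: clean, contaminated, contaminated-then-pruned.

    Pruning removes every test subject whose cross-cohort PI_HAT against the
    discovery set reaches the cutoff; PI_HAT uses a subset of
    ``kinship_loci`` markers (plenty for duplicate separation).
    """
    rows = []
    for rep in range(replicates):
        cseed = _cell_seed(seed, 0, rep)
        cfg = _config_for(config, n_discovery + n_test, cseed)
        panel, pheno, _ = simulate_cohort(cfg, "binary")
        pair = build_cohorts(panel, pheno, n_discovery, n_test, 0.0, seed=cseed)
        covars = pair.discovery_pheno.covariate_names()
        selection = build_prs(pair.discovery_panel, pair.discovery_pheno, covars, "binary")

        dm_clean = _evaluate_cell(
            selection, pair.test_panel, pair.test_pheno, covars, "binary", n_pcs, pc_seed=cseed
        )
        t_panel, t_pheno, injected = inject_overlap(
            pair.test_panel,
            pair.test_pheno,
            pair.discovery_panel,
            pair.discovery_pheno,
            contamination,
            seed=_cell_seed(seed, 1, rep),
        )
        dm_cont = _evaluate_cell(selection, t_panel, t_pheno, covars, "binary", n_pcs, pc_seed=cseed)

        marker_ids = pair.discovery_panel.variants["variant_id"].tolist()[:kinship_loci]
        p_panel, p_pheno, report = kinship.prune_overlap(
            t_panel.subset_variants(marker_ids),
            t_pheno,
            pair.discovery_panel.subset_variants(marker_ids),
            pi_hat_cutoff,
        )
        pruned_ids = p_panel.sample_ids
        dm_pruned = _evaluate_cell(
            selection, t_panel.subset_samples(pruned_ids), p_pheno, covars, "binary",
            n_pcs, pc_seed=cseed,
        )
        rows.append(
            {
                "replicate": rep,
                "seed": cseed,
                "clean_delta_auc": dm_clean.delta_auc,
                "contaminated_delta_auc": dm_cont.delta_auc,
                "pruned_delta_auc": dm_pruned.delta_auc,
                "n_injected": len(injected),
                "n_removed": len(report),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3. scale effect (discovery size sweep, quantitative trait)


def scale_experiment(
    config: SimulationConfig,
    discovery_sizes: tuple[int, ...] = (1000, 3000, 9000),
    n_test: int = 2000,
    replicates: int = 10,
    seed: int = 0,
    n_pcs: int = 20,
) -> ExperimentGrid:
    """ΔR² as a function of discovery-set size, with a fitted per-sample slope.

    The test set is fixed within a replicate; the discovery set is resampled
    at each size.  The grid's ``extras`` carry the least-squares slope of
    mean ΔR² on discovery n, per sample and per 3k samples.
    """
    sizes = sorted(discovery_sizes)
    rows = []
    for rep in range(replicates):
        cseed = _cell_seed(seed, 0, rep)
        cfg = _config_for(config, max(sizes) + n_test, cseed)
        panel, pheno, _ = simulate_cohort(cfg, "quantitative")
        pair_max = build_cohorts(panel, pheno, max(sizes), n_test, 0.0, seed=cseed)
        covars = pair_max.discovery_pheno.covariate_names()
        test_pcs = compute_pcs(
            pair_max.test_panel, min(n_pcs, n_test - 1), seed=cseed
        )
        disc_ids = pair_max.discovery_panel.sample_ids
        rng = np.random.default_rng(np.random.SeedSequence(_cell_seed(seed, 1, rep)))
        for si, n_d in enumerate(sizes):
            sub_ids = [disc_ids[i] for i in rng.choice(len(disc_ids), n_d, replace=False)] \
                if n_d < len(disc_ids) else list(disc_ids)
            d_panel = pair_max.discovery_panel.subset_samples(sub_ids)
            d_pheno = pair_max.discovery_pheno.subset(sub_ids)
            selection = build_prs(d_panel, d_pheno, covars, "quantitative")
            prs = score(pair_max.test_panel, selection)
            dm = evalmetrics.evaluate(
                prs, pair_max.test_pheno, test_pcs, "quantitative", covars, n_pcs=n_pcs
            )
            rows.append(
                {"point": n_d, "replicate": rep, "seed": cseed, **_metrics_row(dm, "quantitative")}
            )
    cells = pd.DataFrame(rows)
    means = cells.groupby("point")["delta_r2"].mean()
    slope = float(np.polyfit(means.index.to_numpy(float), means.to_numpy(), 1)[0])
    extras = {"slope_per_sample": slope, "slope_per_3k": slope * 3000.0}
    return ExperimentGrid("scale", "n_discovery", cells, extras)


# ---------------------------------------------------------------------------
# 4. SNP-count sweep (top-k by ascending P)


def snp_count_sweep(
    config: SimulationConfig,
    ks: tuple[int, ...] = (10, 100, 1000),
    n_discovery: int = 3000,
    n_test: int = 1000,
    replicates: int = 10,
    seed: int = 0,
    trait_type: str = "quantitative",
    n_pcs: int = 20,
) -> ExperimentGrid:
    """ΔAUC/ΔR² as the number of retained SNPs grows (lowest P first)."""
    ks = sorted(ks)
    rows = []
    for rep in range(replicates):
        cseed = _cell_seed(seed, 0, rep)
        cfg = _config_for(config, n_discovery + n_test, cseed)
        panel, pheno, _ = simulate_cohort(cfg, trait_type)
        pair = build_cohorts(panel, pheno, n_discovery, n_test, 0.0, seed=cseed)
        covars = pair.discovery_pheno.covariate_names()
        selection = build_prs(pair.discovery_panel, pair.discovery_pheno, covars, trait_type)
        test_pcs = compute_pcs(pair.test_panel, min(n_pcs, n_test - 1), seed=cseed)
        for k in ks:
            k_eff = min(k, len(selection))
            if k_eff < k:
                logger.info("k=%d capped at %d available SNPs", k, k_eff)
            if k_eff == 0:
                dm = evalmetrics.DeltaMetrics(delta_auc=0.0, delta_r2=0.0, delong_p=1.0, r2_p=1.0)
            else:
                prs = score(pair.test_panel, select_top(selection, k_eff))
                dm = evalmetrics.evaluate(
                    prs, pair.test_pheno, test_pcs, trait_type, covars, n_pcs=n_pcs
                )
            rows.append(
                {"point": k, "replicate": rep, "seed": cseed, "k_used": k_eff,
                 **_metrics_row(dm, trait_type)}
            )
    return ExperimentGrid("snp_count", "n_snps", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# 5. power curve over test-set size


def power_curve(
    config: SimulationConfig,
    n_discovery: int = 3000,
    test_sizes: tuple[int, ...] = (200, 400, 800, 1600),
    alpha: float = 0.01,
    power_target: float = 0.8,
    replicates: int = 20,
    seed: int = 0,
    n_pcs: int = 20,
) -> tuple[pd.DataFrame, int | None]:
    """Fraction of replicates with DeLong p < alpha, per test-set size.

    Returns the power curve and the smallest grid size reaching
    ``power_target`` (None if no grid point does).  Test sets of each size
    are nested subsets of the largest, so the curve is paired across sizes.
    """
    sizes = sorted(test_sizes)
    rows = []
    for rep in range(replicates):
        cseed = _cell_seed(seed, 0, rep)
        cfg = _config_for(config, n_discovery + max(sizes), cseed)
        panel, pheno, _ = simulate_cohort(cfg, "binary")
        pair = build_cohorts(panel, pheno, n_discovery, max(sizes), 0.0, seed=cseed)
        covars = pair.discovery_pheno.covariate_names()
        selection = build_prs(pair.discovery_panel, pair.discovery_pheno, covars, "binary")
        test_ids = pair.test_panel.sample_ids
        for n_t in sizes:
            sub = test_ids[:n_t]
            t_panel = pair.test_panel.subset_samples(sub)
            t_pheno = pair.test_pheno.subset(sub)
            if t_pheno.phenotype.sum() in (0, len(sub)):
                logger.warning("test subset of %d has one class; cell marked failed", n_t)
                rows.append({"point": n_t, "replicate": rep, "seed": cseed,
                             "delta_auc": np.nan, "p": np.nan, "significant": np.nan})
                continue
            dm = _evaluate_cell(selection, t_panel, t_pheno, covars, "binary", n_pcs, pc_seed=cseed)
            rows.append(
                {"point": n_t, "replicate": rep, "seed": cseed,
                 "delta_auc": dm.delta_auc, "p": dm.delong_p,
                 "significant": float(dm.delong_p < alpha)}
            )
    cells = pd.DataFrame(rows)
    curve = (
        cells.groupby("point")
        .agg(power=("significant", "mean"), n_replicates=("replicate", "count"))
        .reset_index()
        .rename(columns={"point": "n_test"})
    )
    reaching = curve.loc[curve["power"] >= power_target, "n_test"]
    minimal = int(reaching.min()) if len(reaching) else None
    return curve, minimal


# ---------------------------------------------------------------------------
# 6. case:control ratio with fixed case count


def ratio_experiment(
    config: SimulationConfig,
    n_cases: int = 1500,
    ratios: tuple[float, ...] = (0.33, 1.0, 3.0),
    n_test: int = 800,
    replicates: int = 10,
    seed: int = 0,
    n_pcs: int = 20,
) -> ExperimentGrid:
    """Vary the discovery control:case ratio with the case count held fixed.

    The ratio axis is controls per case; total discovery n = cases x
    (1 + ratio) is recorded per cell.  The test set is fixed within a
    replicate and disjoint from every discovery arm.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    max_controls = int(np.ceil(max(ratios) * n_cases))
    rows = []
    for rep in range(replicates):
        cseed = _cell_seed(seed, 0, rep)
        # pool sized so the rarest class is sufficient with margin
        need_cases = n_cases + n_test
        need_controls = max_controls + n_test
        n_pool = int(1.25 * max(need_cases / config.prevalence,
                                need_controls / (1.0 - config.prevalence)))
        cfg = _config_for(config, n_pool, cseed)
        panel, pheno, _ = simulate_cohort(cfg, "binary")
        y = pheno.phenotype
        ids = np.asarray(pheno.sample_ids)
        rng = np.random.default_rng(np.random.SeedSequence(cseed))
        case_ids = rng.permutation(ids[y == 1])
        control_ids = rng.permutation(ids[y == 0])
        if len(case_ids) < need_cases or len(control_ids) < need_controls:
            raise ValueError("pool too small for the requested ratio design")
        # fixed test set: prevalence-matched sample, disjoint from discovery
        n_test_cases = round(n_test * config.prevalence)
        test_ids = np.concatenate(
            [case_ids[:n_test_cases], control_ids[: n_test - n_test_cases]]
        ).tolist()
        disc_cases = case_ids[n_test_cases : n_test_cases + n_cases]
        avail_controls = control_ids[n_test - n_test_cases :]
        t_panel = panel.subset_samples(test_ids)
        t_pheno = pheno.subset(test_ids)
        covars = t_pheno.covariate_names()
        test_pcs = compute_pcs(t_panel, min(n_pcs, n_test - 1), seed=cseed)
        for ratio in ratios:
            n_controls = int(round(ratio * n_cases))
            disc_ids = np.concatenate([disc_cases, avail_controls[:n_controls]]).tolist()
            d_panel = panel.subset_samples(disc_ids)
            d_pheno = pheno.subset(disc_ids)
            selection = build_prs(d_panel, d_pheno, covars, "binary")
            prs = score(t_panel, selection)
            dm = evalmetrics.evaluate(prs, t_pheno, test_pcs, "binary", covars, n_pcs=n_pcs)
            rows.append(
                {"point": ratio, "replicate": rep, "seed": cseed,
                 "n_discovery_total": n_cases + n_controls,
                 **_metrics_row(dm, "binary")}
            )
    return ExperimentGrid("case_control_ratio", "control_case_ratio", pd.DataFrame(rows))
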