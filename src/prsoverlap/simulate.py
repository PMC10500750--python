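"""Synthetic cohorts with LD, polygenic traits and controlled subject overlap.

The generator stands in for the cohort data a PRS study would use: biallelic
SNP dosages with blockwise LD (an exchangeable-correlation Gaussian copula per
block, thresholded to genotypes at Hardy-Weinberg quantiles), an additive
polygenic architecture at a configured narrow-sense heritability h2, binary
traits via the liability-threshold model at prevalence K, nuisance covariates,
and discovery/test cohort pairs sharing a controllable fraction of identical
subjects or planted relatives.

All randomness flows from ``SimulationConfig.seed``; the same config yields
bit-identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .formats import GenotypePanel, PhenotypeTable

logger = logging.getLogger(__name__)

#: default covariate architecture: (generator, effect size on the liability /
#: phenotype scale).  age and sex are pure nuisance by default; the apoe4
#: analog carries real risk so reference single-covariate models are
#: informative.
DEFAULT_COVARIATE_SPEC: dict[str, float] = {"age": 0.0, "sex": 0.0, "apoe4": 0.0}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    h2 is narrow-sense heritability of the liability (height 0.497 and
    hypertension 0.147 are the field's reference points for high/moderate
    values); prevalence is the binary-trait population prevalence K.
    """

    n_samples: int = 2000
    n_variants: int = 5000
    block_size: int = 20
    rho: float = 0.6
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_causal: int = 200
    h2: float = 0.3
    prevalence: float = 0.3
    covariate_spec: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SPEC))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal exceeds n_variants")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed))


@dataclass
class EffectVector:
    """True architecture: per-variant effects and per-sample liabilities.

    beta_true acts on standardized dosages, so var(g) = h2 in expectation
    irrespective of the MAF spectrum.  liability = g + e with
    e ~ N(0, 1 - h2).
    """

    beta_true: np.ndarray
    g: np.ndarray
    e: np.ndarray

    @property
    def liability(self) -> np.ndarray:
        return self.g + self.e


@dataclass
class CohortPair:
    """Discovery/test cohorts possibly sharing subjects."""

    discovery_panel: GenotypePanel
    discovery_pheno: PhenotypeTable
    test_panel: GenotypePanel
    test_pheno: PhenotypeTable
    overlap_ids: list[str]
    related_pairs: list[tuple[str, str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw a dosage panel with blockwise exchangeable-correlation LD.

    Within each block of ``block_size`` variants, a latent Gaussian
    z = sqrt(rho) * c + sqrt(1 - rho) * eps (c common per sample per block) is
    thresholded at the Hardy-Weinberg genotype quantiles of each variant's
    MAF, so marginals are HWE and within-block dosages are correlated; blocks
    are independent.  Variants are placed 5 kb apart so a +-1 Mb clumping
    window spans many blocks.
    """
    rng = config.rng() if rng is None else rng
    n, m = config.n_samples, config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    dosage = np.empty((n, m), dtype=np.float64)
    sr, se = np.sqrt(config.rho), np.sqrt(1.0 - config.rho)
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        width = stop - start
        common = rng.standard_normal((n, 1))
        z = sr * common + se * rng.standard_normal((n, width))
        p = maf[start:stop]
        # HWE cumulative genotype probabilities for dosage counted allele p
        t0 = norm.ppf((1.0 - p) ** 2)
        t1 = norm.ppf((1.0 - p) ** 2 + 2.0 * p * (1.0 - p))
        dosage[:, start:stop] = (z > t0).astype(np.float64) + (z > t1)

    spacing = 5_000
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1, dtype=np.int64) * spacing,
            "allele_counted": "A",
            "allele_other": "G",
        }
    )
    sample_ids = [f"S{i + 1}" for i in range(n)]
    return GenotypePanel(variants, sample_ids, dosage)


def _standardize(dosage: np.ndarray) -> np.ndarray:
    freq = np.nanmean(dosage, axis=0) / 2.0
    sd = np.sqrt(2.0 * freq * (1.0 - freq))
    sd[sd == 0] = 1.0
    return (dosage - 2.0 * freq) / sd


def assign_effects(
    panel: GenotypePanel, config: SimulationConfig, rng: np.random.Generator | None = None
) -> EffectVector:
    """Sample causal variants and build genetic / environmental values.

    Causal variants are a uniform subset of size n_causal; effects on
    standardized dosages are N(0, h2 / n_causal); e ~ N(0, 1 - h2).
    """
    rng = config.rng() if rng is None else rng
    m = panel.n_variants
    beta = np.zeros(m)
    causal = rng.choice(m, size=config.n_causal, replace=False)
    if config.h2 > 0:
        beta[causal] = rng.normal(0.0, np.sqrt(config.h2 / config.n_causal), size=config.n_causal)
    g = _standardize(panel.dosage) @ beta
    e = rng.normal(0.0, np.sqrt(1.0 - config.h2), size=panel.n_samples)
    return EffectVector(beta_true=beta, g=g, e=e)


def _generate_covariates(
    n: int, spec: dict[str, float], rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Emit covariate columns and their summed contribution to the liability.

    age ~ N(0,1) (standardized), sex ~ Bernoulli(0.5), apoe4 ~ Bernoulli(0.3),
    center ~ Bernoulli(0.5); all independent of genotype, so any principal
    components are pure nuisance.
    """
    cols: dict[str, np.ndarray] = {}
    contribution = np.zeros(n)
    for name, coef in spec.items():
        if name == "age":
            x = rng.standard_normal(n)
        elif name in ("sex", "center"):
            x = rng.integers(0, 2, size=n).astype(float)
        elif name == "apoe4":
            x = (rng.random(n) < 0.3).astype(float)
        else:
            raise ValueError(f"unknown covariate {name!r} in covariate_spec")
        cols[name] = x
        contribution += coef * x
    return pd.DataFrame(cols), contribution


def _covariate_variance(spec: dict[str, float]) -> float:
    var = 0.0
    for name, coef in spec.items():
        if name == "age":
            v = 1.0
        elif name in ("sex", "center"):
            v = 0.25
        elif name == "apoe4":
            v = 0.3 * 0.7
        else:
            v = 1.0
        var += coef * coef * v
    return var


def simulate_phenotype(
    panel: GenotypePanel,
    effects: EffectVector,
    config: SimulationConfig,
    trait_type: str = "binary",
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Turn liabilities into a phenotype table with covariates.

    Binary traits: case iff liability (plus covariate contributions) exceeds
    the threshold Phi^-1(1 - K) scaled by the model-implied liability SD, so
    realized prevalence tracks K whatever covariate effects are configured.
    Quantitative traits: phenotype = liability + covariate contributions.
    """
    rng = config.rng() if rng is None else rng
    n = panel.n_samples
    covariates, contribution = _generate_covariates(n, config.covariate_spec, rng)
    liability = effects.liability + contribution

    if trait_type == "binary":
        scale = np.sqrt(1.0 + _covariate_variance(config.covariate_spec))
        threshold = norm.ppf(1.0 - config.prevalence) * scale
        phenotype = (liability > threshold).astype(int)
        if phenotype.sum() == 0 or phenotype.sum() == n:
            raise ValueError(
                f"prevalence K={config.prevalence} produced a single-class phenotype "
                f"at n={n}; use a larger sample"
            )
    elif trait_type == "quantitative":
        phenotype = liability
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")

    table = pd.DataFrame({"sample_id": panel.sample_ids, "phenotype": phenotype})
    for c in covariates.columns:
        table[c] = covariates[c].to_numpy()
    return PhenotypeTable(table, trait_type)


def simulate_cohort(
    config: SimulationConfig, trait_type: str = "binary"
) -> tuple[GenotypePanel, PhenotypeTable, EffectVector]:
    """Convenience: genotypes, effects and phenotypes from one seed."""
    rng = config.rng()
    panel = simulate_genotypes(config, rng)
    effects = assign_effects(panel, config, rng)
    pheno = simulate_phenotype(panel, effects, config, trait_type, rng)
    return panel, pheno, effects


# ---------------------------------------------------------------------------
# cohort assembly


def build_cohorts(
    panel_pool: GenotypePanel,
    pheno_pool: PhenotypeTable,
    n_discovery: int,
    n_test: int,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> CohortPair:
    """Split a pool into discovery and test cohorts with controlled overlap.

    round(overlap_fraction * n_test) test subjects are copied verbatim from
    the discovery set (identical ID, genotype and phenotype — the same person
    measured twice); the remainder is disjoint from discovery.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1], got {overlap_fraction}")
    n_overlap = round(overlap_fraction * n_test)
    n_fresh = n_test - n_overlap
    need = n_discovery + n_fresh
    if need > panel_pool.n_samples:
        raise ValueError(
            f"pool of {panel_pool.n_samples} too small: need n_discovery + "
            f"n_test*(1 - overlap_fraction) = {need}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(panel_pool.n_samples)
    disc_idx = perm[:n_discovery]
    fresh_idx = perm[n_discovery : n_discovery + n_fresh]
    ov_idx = rng.choice(disc_idx, size=n_overlap, replace=False)
    test_idx = np.concatenate([fresh_idx, ov_idx]).astype(int)

    ids = np.asarray(panel_pool.sample_ids)
    disc_ids = ids[disc_idx].tolist()
    test_ids = ids[test_idx].tolist()
    return CohortPair(
        discovery_panel=panel_pool.subset_samples(disc_ids),
        discovery_pheno=pheno_pool.subset(disc_ids),
        test_panel=panel_pool.subset_samples(test_ids),
        test_pheno=pheno_pool.subset(test_ids),
        overlap_ids=ids[ov_idx].tolist(),
    )


def inject_overlap(
    test_panel: GenotypePanel,
    test_pheno: PhenotypeTable,
    discovery_panel: GenotypePanel,
    discovery_pheno: PhenotypeTable,
    fraction: float,
    seed: int = 0,
) -> tuple[GenotypePanel, PhenotypeTable, list[str]]:
    """Replace round(fraction * n_test) test subjects with discovery subjects.

    Replacement preserves test-set size; the injected subjects keep their
    discovery IDs.  Returns (panel, phenotypes, injected_ids).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    n_test = test_panel.n_samples
    n_replace = round(fraction * n_test)
    if n_replace == 0:
        return test_panel, test_pheno, []
    if n_replace > discovery_panel.n_samples:
        raise ValueError(
            f"discovery set of {discovery_panel.n_samples} cannot supply {n_replace} subjects"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    replace_rows = rng.choice(n_test, size=n_replace, replace=False)
    donor_rows = rng.choice(discovery_panel.n_samples, size=n_replace, replace=False)

    ids = np.asarray(test_panel.sample_ids, dtype=object)
    dosage = test_panel.dosage.copy()
    ids[replace_rows] = np.asarray(discovery_panel.sample_ids, dtype=object)[donor_rows]
    dosage[replace_rows] = discovery_panel.dosage[donor_rows]

    pheno_tab = test_pheno.table.copy()
    donor_tab = discovery_pheno.table.iloc[donor_rows].reset_index(drop=True)
    for col in pheno_tab.columns:
        pheno_tab.loc[replace_rows, col] = donor_tab[col].to_numpy()

    panel = GenotypePanel(test_panel.variants.copy(), ids.tolist(), dosage)
    return panel, PhenotypeTable(pheno_tab, test_pheno.trait_type), ids[replace_rows].tolist()


def spawn_relative(
    genotype: np.ndarray,
    relationship: str,
    mafs: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Create a relative's dosage vector for a given genotype.

    duplicate: identical copy.  parent_offspring: one allele transmitted from
    the source genotype, one drawn at the population frequency, independently
    per variant.  full_sib: the source's two parents are simulated
    conditionally (each contributes one of the source's alleles plus a
    population allele) and a second child is drawn from them.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    d = np.asarray(genotype, dtype=float)
    if np.isnan(d).any():
        raise ValueError("spawn_relative requires complete dosages")
    p = np.asarray(mafs, dtype=float)
    if relationship == "duplicate":
        return d.copy()
    # split the source genotype into two alleles (order randomized for hets)
    a1 = np.where(d == 2, 1.0, np.where(d == 0, 0.0, rng.integers(0, 2, size=d.shape)))
    a2 = d - a1
    if relationship == "parent_offspring":
        transmitted = np.where(rng.random(d.shape) < 0.5, a1, a2)
        other = (rng.random(d.shape) < p).astype(float)
        return transmitted + other
    if relationship == "full_sib":
        # parent A carries (a1, x), parent B carries (a2, y)
        x = (rng.random(d.shape) < p).astype(float)
        y = (rng.random(d.shape) < p).astype(float)
        from_a = np.where(rng.random(d.shape) < 0.5, a1, x)
        from_b = np.where(rng.random(d.shape) < 0.5, a2, y)
        return from_a + from_b
    raise ValueError(f"unknown relationship {relationship!r}")
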