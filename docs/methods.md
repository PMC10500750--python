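# Methods

## Synthetic cohorts

**Genotypes.** Variants are biallelic SNPs with MAF drawn uniformly from a
configured range (default 0.01–0.5, so every variant clears the common-SNP
filter in expectation). LD is blockwise: within each block of `block_size`
variants (default 20) a latent Gaussian `z = √ρ·c + √(1−ρ)·ε` (block-common
`c` per sample) is thresholded at each variant's Hardy–Weinberg genotype
quantiles, giving HWE marginals, exchangeable within-block dosage
correlation controlled by `ρ` (default 0.6), and exact independence across
blocks. Variants are placed 5 kb apart on one chromosome so a ±1 Mb
clumping window spans many blocks. This is the simplest LD model that makes
clumping non-trivial; realistic recombination maps, population structure,
genotyping error and the X chromosome are deliberately out of scope, so
passing tests show the machinery is correct, not that real-cohort LD is
captured.

**Architecture.** `n_causal` variants (default 200) are a uniform subset;
effects on *standardized* dosages are N(0, h²/n_causal), so the genetic
variance is h² in expectation regardless of the MAF spectrum and of LD
(within-block correlation cancels in expectation because the correlation
matrix has unit diagonal). Environmental noise is N(0, 1−h²); the liability
is their sum. h² reference points used in the experiments: 0.3 for the
binary designs (between the hypertension-like 0.147 and height-like 0.497
regimes) and 0.5 for the quantitative scale-effect design.

**Phenotypes.** Binary traits follow the liability-threshold model: case
iff liability > Φ⁻¹(1−K)·σ, where σ is the model-implied liability SD
including any covariate effects, so realized prevalence tracks K whatever
nuisance effects are configured. Default prevalence 0.3 (the case fractions
of the AD consortia this emulates run 24–61%). Quantitative traits are the
liability itself plus covariate effects. Covariates (age ~ N(0,1), sex and
center ~ Bernoulli(½), an apoe4-like risk allele carrier flag ~
Bernoulli(0.3)) are independent of genotype, so principal components are
pure nuisance by design. The experiment-level default gives the apoe4
analog a liability effect of 0.5 and age/sex 0.1, making the
single-covariate reference model informative while leaving the trait
polygenic.

**Overlap and relatives.** Discovery/test pairs share
`round(fraction·n_test)` subjects copied verbatim (same ID, genotype,
phenotype — one person measured twice; cross-platform genotype discordance
is not modeled). `spawn_relative` plants duplicates (identical vector),
parent-offspring pairs (one allele transmitted per locus, one drawn at the
population frequency) and full siblings (the source's two parents are
simulated conditionally and a second child drawn), giving expected PI_HAT
1, 0.5 and 0.5. All randomness descends from a single seed; identical
configuration gives bit-identical cohorts.

## Association scan

Per-variant regressions of phenotype on dosage plus covariates: logistic
IRLS for binary traits (convergence when the max coefficient change is
below 1e-8, 25-iteration cap, separation left flagged non-converged, Wald
two-sided p), exact OLS via Frisch–Waugh residualization for quantitative
traits. The covariate block is shared across variants, so the per-variant
Newton systems are assembled with batched tensor contractions and solved
together; a scan of 5000 variants at n = 3000 takes seconds. Monomorphic
and all-missing variants are reported with β = 0, p = 1 and flagged;
missing dosages are mean-imputed for fitting (the simulator emits complete
data; this path exists for file inputs). PCs come from randomized SVD of
the standardized dosage matrix with a fixed seed and a deterministic sign
convention (largest-magnitude loading positive); 20 PCs is the evaluation
default.

## C+T scoring

Filters: MAF ≥ 0.01, P ≤ 0.5, exclusion intervals 1-based inclusive on
both ends (the APOE-region analog). Clumping is greedy from the lowest P
(ties broken by chromosome, position, variant id for determinism): keep the
index SNP, drop every not-yet-kept variant within ±1 Mb on the same
chromosome with dosage r² ≥ 0.1 against it, repeat. r² is the squared
Pearson correlation in the designated LD panel — the discovery panel by
default, with the test panel selectable for summary-statistics-only runs.
Scoring sums β × effect-allele dosage; if the panel counts the other
allele the dosage is reflected (2−d); strand-ambiguous pairs (A/T, C/G)
are dropped; missing dosages are imputed as 2 × effect-allele frequency
(PLINK-style mean imputation).

## Kinship

The moments estimator solves observed IBS-state counts against their HWE
expectations for P(IBD=0/1/2), clamps negatives to zero, renormalizes, and
reports PI_HAT = P(IBD=2) + ½·P(IBD=1). Allele frequencies come from the
pooled panel pair by default (external frequencies can be supplied). The
small-sample frequency bias corrections some implementations apply are
omitted; with ≥ 2000 informative loci the estimator separates duplicates
from unrelated pairs with a wide margin, which is the regime pruning
operates in. Pairs sharing fewer than 100 informative loci are flagged
unstable. All-pairs IBS counting is three indicator-matrix products in
float32, so desk-scale cohort pairs take seconds. Pruning removes every
test subject whose maximum cross-cohort PI_HAT reaches the cutoff; the
cutoff is a required parameter (0.9 in the experiments, comfortably above
the unrelated tail and below first-degree relatives).

## Evaluation

Model II (covariates + PCs) and Model III (Model II + PRS) are fitted by
statsmodels GLM/OLS; the linear predictor is the risk score. Binary gains:
rank-based AUC with midrank ties, DeLong's paired test via structural
components, Nagelkerke pseudo-R² with the intercept-only baseline for both
models (matching the R `fmsb` convention), ΔR² their difference.
Quantitative gains: Δadjusted-R² with the extra-sum-of-squares F test. A
constant (or dropped) PRS makes Model III collapse to Model II, returning
exact zeros; a degenerate DeLong variance returns p = 1 by convention.
Stratified k-fold splitting (default 10-fold, 9:1) deals shuffled samples
round-robin within the cross-classification of the stratification columns
(continuous columns binned into quintiles; strata smaller than k merged
with a warning), so per-fold stratum counts differ by at most one.

## Experiment designs and problem sizes

All experiments run the full stack per replicate and summarize mean ± sd
per grid point; per-cell seeds derive from the master seed by SeedSequence
spawn keys and are recorded in the output, so any cell is re-runnable in
isolation. Desk-scale defaults — 2000–5000 variants in blocks of 20 at
ρ = 0.6, 200 causal, discovery n = 3000, test n = 800 — were chosen so a
full design completes in minutes on one CPU while keeping every effect
far larger than its Monte-Carlo error; the paper-scale cohort sizes
(tens to hundreds of thousands) change the magnitudes but not the laws the
tests assert (monotone leakage inflation, prune-repair, positive scale
slope, SNP-count plateau).

* **Contamination**: overlap fraction 0→1 by 0.1; the discovery GWAS and
  SNP selection are fitted once per replicate, the test set re-contaminated
  and re-evaluated per fraction; a single-covariate reference model (the
  apoe4 analog alone over Model II without it) is the stability control.
* **Prune-repair**: arms clean / contaminated (30%) / pruned (PI_HAT ≥ 0.9,
  2000-marker kinship subset — ample for duplicate separation).
* **Scale**: quantitative h² = 0.5, discovery sizes 1k/3k/9k resampled from
  one pool, fixed 2k test set; the slope of mean ΔR² on discovery n is
  reported per sample and per 3k samples.
* **SNP count**: top-k subsets of one clumped selection, k ascending.
* **Power**: fraction of replicates with DeLong p < 0.01 per test size
  (nested subsets, so the curve is paired); "sufficient power" is
  operationalized as ≥ 0.8.
* **Case:control ratio**: cases fixed (default 1500 at desk scale),
  controls = ratio × cases, fixed prevalence-matched test set.

−log₁₀(P) values are floored at P = 1e-300 in grids.

## Numerical conventions

Coordinates are 1-based inclusive everywhere (PLINK/VCF convention). The
traw dialect is tab-separated with header `CHR SNP CM POS COUNTED ALT` then
sample IDs; dosage counts the COUNTED allele; missing is `NA`. VCF reading
is restricted to biallelic SNPs with GT (ALT is the counted allele);
summary-statistics TSVs accept `BETA` or `OR` (log-transformed on read).
Variant sort by (chromosome, position) is the only reordering readers
perform, and it is logged; sample order is never changed silently.

## Known limitations

No population structure or admixture (PCs therefore capture noise, which
is the intended null for the nuisance adjustment), no genotyping error or
imputation dosages, no cross-platform measurement discordance for
overlapping subjects, no penalized-regression scores. The PI_HAT estimator
assumes HWE and a homogeneous population — the same assumptions under
which the cutoff conventions it reproduces were derived.
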