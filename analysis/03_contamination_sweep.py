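"""Contamination sweep: discovery subjects replace 0..100% of the test set.

The headline experiment: ΔAUC of the PRS term inflates monotonically as the
overlap fraction grows, while a single-covariate reference model stays flat.
Writes the per-cell grid and the mean ± sd summary under results/.
"""

from pathlib import Path

from scipy import stats

import prsoverlap as po
from prsoverlap.experiments import EXPERIMENT_COVARIATES, contamination_experiment
from prsoverlap.formats import write_table

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

cfg = po.SimulationConfig(
    n_variants=2000, h2=0.3, covariate_spec=dict(EXPERIMENT_COVARIATES), seed=0
)
grid = contamination_experiment(cfg, n_discovery=3000, n_test=800,
                                replicates=5, seed=11)
summ = grid.summary()
write_table(grid.cells, OUT / "contamination_cells.tsv")
write_table(summ, OUT / "contamination_summary.tsv")

rho, _ = stats.spearmanr(summ["overlap_fraction"], summ["mean_delta_auc"])
m0 = summ.loc[summ["overlap_fraction"] == 0.0, "mean_delta_auc"].iloc[0]
m1 = summ.loc[summ["overlap_fraction"] == 1.0, "mean_delta_auc"].iloc[0]
ref_range = (grid.cells.groupby("point")["ref_delta_auc"].mean().max()
             - grid.cells.groupby("point")["ref_delta_auc"].mean().min())

print(summ.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nmean delta_auc inflates {m0:.4f} -> {m1:.4f} as overlap goes 0 -> 100% "
      f"(Spearman rho = {rho:.3f})")
print(f"single-covariate reference model varies by only {ref_range:.4f} across the sweep")
print(f"wrote {OUT}/contamination_*.tsv")
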