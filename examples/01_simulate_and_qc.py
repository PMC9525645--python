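"""Simulate a matched tumor/normal cohort and apply the QC filters.

The generator plants nothing here; the printout shows the cohort's shape
and how many cells the UMI and doublet-score filters remove.
"""
import numpy as np

from scduet import filter_cells
from scduet.simulate import SimulationConfig, simulate_cohort

cm, truth = simulate_cohort(SimulationConfig(
    n_samples_per_condition=5, cells_mean=300, n_genes=500,
    doublet_rate=0.06, seed=1))
print(f"cohort: {cm.n_cells} cells x {cm.n_genes} genes, "
      f"{cm.obs['sample'].nunique()} samples")
print(f"median UMI per cell: {np.median(cm.total_umi):.0f}")

filtered = filter_cells(cm, min_umi=700, max_doublet=0.4)
print(f"after QC (UMI >= 700, doublet <= 0.4): {filtered.n_cells} cells "
      f"({cm.n_cells - filtered.n_cells} removed)")
# Cells failing either rule are low-coverage droplets or likely doublets;
# everything downstream runs on the filtered matrix.
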