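"""Marker calling, pseudobulk differential expression, and the two-round
metastatic-signature selection.

A gene is planted high in tumor subclone C4 only; a second gene is planted
in C4 *and* in macrophages. Round 1 (C4 vs other subclones) keeps both;
round 2 (C4 vs every non-tumor population) must drop the shared one.
"""
import numpy as np
import pandas as pd
import scipy.sparse as sp

from scduet import normalize
from scduet.markers import marker_genes, pseudobulk_de, select_metastatic_signature
from scduet.distance import make_pseudobulk
from scduet.simulate import SimulationConfig, simulate_cohort

cm, _ = simulate_cohort(SimulationConfig(
    n_samples_per_condition=3, cells_mean=400, n_genes=120, seed=8))
rng = np.random.default_rng(8)

tumor_cells = cm.obs.index[cm.obs["cell_type"] == "tumor"]
subclones = pd.Series(rng.choice(["C1", "C2", "C3", "C4"], size=len(tumor_cells)),
                      index=tumor_cells)
counts = cm.counts.toarray()
gi = {g: i for i, g in enumerate(cm.gene_ids)}
pos = {c: i for i, c in enumerate(cm.cell_ids)}
c4 = [pos[c] for c in subclones.index[subclones == "C4"]]
macro = [pos[c] for c in cm.obs.index[cm.obs["cell_type"] == "macrophage"]]
counts[gi["G0100"], c4] += rng.poisson(20, size=len(c4))          # C4-specific
counts[gi["G0101"], c4] += rng.poisson(20, size=len(c4))          # shared ...
counts[gi["G0101"], macro] += rng.poisson(25, size=len(macro))    # ... with macro
cm.counts = sp.csc_matrix(counts)
nm = normalize(cm)

table = marker_genes(nm, cm.obs["cell_type"])
print("markers per cell type (Z > 3):")
print(table.groupby("cluster")["is_marker"].sum().to_string())

sel = select_metastatic_signature(nm, subclones, target="C4", top_n=12)
print(f"\nround 1 top genes: {sel.round1_top[:5]} ...")
print(f"selected signature: {sel.final.genes}")
print(f"C4-specific G0100 selected: {'G0100' in sel.final.genes}; "
      f"macrophage-shared G0101 excluded: {'G0101' not in sel.final.genes}")

cond = cm.obs.groupby("sample")["condition"].agg(lambda s: s.mode().iat[0])
de = pseudobulk_de(make_pseudobulk(cm), cond, "tumor")
print(f"\npseudobulk DE (tumor cells, tumor vs normal): "
      f"{int((de['p_adj'] < 0.05).sum())} genes at FDR 5% "
      f"(none planted, so this should be ~0)")
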