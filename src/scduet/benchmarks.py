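"""Desk-scale calibration and recovery benchmarks.

Every statistic in the pipeline is exercised against the synthetic
generator's ground truth in two regimes: exchangeable (null) cohorts, where
false-positive rates at nominal 0.05 must stay controlled, and
planted-effect cohorts, where the planted signal must be recovered. These
functions are the package's acceptance surface; the replicate counts and
cohort sizes used by the test suite and the acceptance script are desk-scale
choices documented in the methods note.

All randomness derives from the ``seed`` argument via
``numpy.random.SeedSequence`` spawning, so a run is reproducible end to end.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import abundance, distance, interactions, survival
from .data import GeneSet, normalize
from .simulate import (DEEffect, LRPlant, SimulationConfig, simulate_bulk_survival,
                       simulate_cohort)

log = logging.getLogger(__name__)

__all__ = [
    "null_fpr_proportions",
    "null_fpr_distance",
    "null_fpr_lr",
    "null_density_flag_rate",
    "planted_composition_recovery",
    "planted_distance_recovery",
    "planted_lr_recovery",
    "planted_signature_recovery",
    "survival_power_rate",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _sample_conditions(cm) -> pd.Series:
    return cm.obs.groupby("sample")["condition"].agg(lambda s: s.mode().iat[0])


# ---------------------------------------------------------------------------
# Null calibration (exchangeable cohorts: no planted effects)
# ---------------------------------------------------------------------------

def null_fpr_proportions(n_cohorts: int = 200, seed: int = 0,
                         alpha: float = 0.05) -> float:
    """False-positive rate of the per-type proportion tests on exchangeable
    cohorts (10+10 samples): fraction of (cohort, cell type) tests with
    p < alpha."""
    hits = total = 0
    for s in _child_seeds(seed, n_cohorts):
        cm, _ = simulate_cohort(SimulationConfig(
            n_samples_per_condition=10, cells_mean=60, n_genes=10,
            n_markers_per_type=0, seed=s))
        out = abundance.proportion_tests(cm).dropna(subset=["p"])
        hits += int((out["p"] < alpha).sum())
        total += len(out)
    return hits / total


def null_fpr_distance(n_cohorts: int = 200, seed: int = 0,
                      alpha: float = 0.05, n_perm: int = 199) -> float:
    """False-positive rate of the expression-distance permutation test on
    exchangeable single-type cohorts (4+4 samples)."""
    hits = total = 0
    for s in _child_seeds(seed, n_cohorts):
        cm, _ = simulate_cohort(SimulationConfig(
            n_samples_per_condition=4, cells_mean=60, n_genes=150,
            cell_types={"only": 1.0}, n_markers_per_type=0, seed=s))
        res = distance.celltype_distance(cm, min_cells=10, n_rounds=2, seed=s)
        ps = distance.distance_permutation_test(res, n_perm=n_perm, seed=s + 1)
        hits += int((ps < alpha).sum())
        total += len(ps)
    return hits / total


def null_fpr_lr(n_cohorts: int = 200, seed: int = 0, alpha: float = 0.05,
                n_perm: int = 199, n_pairs: int = 10) -> float:
    """Rate of ligand-receptor triples called at BH-adjusted p < alpha on
    exchangeable cohorts (marker structure present, no planted pairs)."""
    hits = total = 0
    for s in _child_seeds(seed, n_cohorts):
        cm, _ = simulate_cohort(SimulationConfig(
            n_samples_per_condition=2, cells_mean=150, n_genes=60,
            cell_types={"a": 0.4, "b": 0.3, "c": 0.3},
            n_markers_per_type=0, seed=s))
        nm = normalize(cm)
        rng = np.random.default_rng(s)
        picks = rng.choice(cm.gene_ids, size=(n_pairs, 2), replace=False)
        table = interactions.LRPairTable(pd.DataFrame(
            [{"ligand": l, "receptor": r, "pair_id": f"{l}_{r}"}
             for l, r in picks]).drop_duplicates("pair_id"))
        cands = interactions.screen_pairs(nm, table)
        if not len(cands):
            continue
        out = interactions.permutation_test(nm, cands, n_perm=n_perm, seed=s + 1)
        hits += int((out["p_adj"] < alpha).sum())
        total += len(out)
    return hits / total


def null_density_flag_rate(n_cohorts: int = 100, seed: int = 0,
                           gridsize: int = 100, z_crit: float = 1.96) -> float:
    """Fraction of occupied bins with |Z| above ``z_crit`` in the density
    difference map of exchangeable cohorts (5+5 samples)."""
    flagged = total = 0
    for s in _child_seeds(seed, n_cohorts):
        cm, _ = simulate_cohort(SimulationConfig(
            n_samples_per_condition=5, cells_mean=100, n_genes=10,
            n_markers_per_type=0, seed=s))
        dg = abundance.quantile_normalize_grids(
            abundance.estimate_density(cm, gridsize=gridsize))
        dm = abundance.density_diff(dg)
        flagged += int((np.abs(dm.z[dm.mask]) > z_crit).sum())
        total += int(dm.mask.sum())
    return flagged / total


# ---------------------------------------------------------------------------
# Planted-effect recovery
# ---------------------------------------------------------------------------

def planted_composition_recovery(n_runs: int = 100, seed: int = 0,
                                 effect: float = 2.0,
                                 coda_n_boot: int = 400) -> dict[str, float]:
    """Recovery of a doubled cell-type proportion in tumor.

    Returns the fraction of runs with proportion-test p < 0.05 for the
    shifted type, and (from one cohort) the fraction of CoDA bootstrap draws
    with a positive separating coefficient for it.
    """
    seeds = _child_seeds(seed, n_runs)
    sig = 0
    for s in seeds:
        cm, _ = simulate_cohort(SimulationConfig(
            n_samples_per_condition=10, cells_mean=150, n_genes=10,
            n_markers_per_type=0,
            composition_effects={"macrophage": effect}, seed=s))
        out = abundance.proportion_tests(cm).set_index("cell_type")
        sig += out.loc["macrophage", "p"] < 0.05
    cm, _ = simulate_cohort(SimulationConfig(
        n_samples_per_condition=10, cells_mean=150, n_genes=10,
        n_markers_per_type=0, composition_effects={"macrophage": effect},
        seed=seeds[0]))
    counts = cm.obs.groupby(["sample", "cell_type"]).size().unstack(fill_value=0)
    res = abundance.coda_coefficients(counts, _sample_conditions(cm),
                                      n_boot=coda_n_boot, cells_per_boot=1000,
                                      seed=seeds[0])
    return {
        "proportion_significant_rate": sig / n_runs,
        "coda_positive_draw_fraction": float(
            (res.bootstrap_draws["macrophage"] > 0).mean()),
    }


def planted_distance_recovery(n_runs: int = 100, seed: int = 0,
                              log2fc: float = 1.5) -> float:
    """Fraction of runs in which the cell type carrying planted tumor-vs-
    normal DE has the largest normalized expression distance."""
    hits = 0
    genes = [f"G{i:04d}" for i in range(60, 90)]
    for s in _child_seeds(seed, n_runs):
        cm, _ = simulate_cohort(SimulationConfig(
            n_samples_per_condition=5, cells_mean=150, n_genes=250, seed=s,
            de_effects=[DEEffect("tumor", "tumor", genes, log2fc)]))
        res = distance.celltype_distance(cm, n_rounds=3, seed=s)
        nd = res.normalized_distance.dropna()
        hits += len(nd) > 1 and nd.idxmax() == "tumor"
    return hits / n_runs


def planted_lr_recovery(n_runs: int = 50, seed: int = 0, effect: float = 4.0,
                        n_perm: int = 200, n_decoys: int = 10) -> float:
    """Fraction of runs in which a planted sender-ligand / receiver-receptor
    co-elevation is called at BH-adjusted p < 0.05."""
    hits = 0
    for s in _child_seeds(seed, n_runs):
        cm, _ = simulate_cohort(SimulationConfig(
            n_samples_per_condition=3, cells_mean=250, n_genes=150, seed=s,
            lr_plants=[LRPlant("G0100", "macrophage", "G0101", "tcell", effect)]))
        nm = normalize(cm)
        rows = [{"ligand": "G0100", "receptor": "G0101", "pair_id": "planted"}]
        rng = np.random.default_rng(s)
        decoys = rng.choice([g for g in cm.gene_ids
                             if g not in ("G0100", "G0101")],
                            size=(n_decoys, 2), replace=False)
        rows += [{"ligand": l, "receptor": r, "pair_id": f"{l}_{r}"}
                 for l, r in decoys]
        table = interactions.LRPairTable(
            pd.DataFrame(rows).drop_duplicates("pair_id"))
        cands = interactions.screen_pairs(nm, table)
        out = interactions.permutation_test(nm, cands, n_perm=n_perm, seed=s + 1)
        hit = out[(out["pair_id"] == "planted") & (out["sender"] == "macrophage")
                  & (out["receiver"] == "tcell")]
        hits += len(hit) > 0 and bool((hit["p_adj"] < 0.05).iloc[0])
    return hits / n_runs


def planted_signature_recovery(seed: int = 0) -> dict[str, bool]:
    """One synthetic subclone cohort: a gene elevated only in the target
    subclone must enter the selected signature; a gene shared with
    macrophages must be excluded by the specificity round.

    The shared gene is planted at least as high in macrophages as in the
    subclone (a gene exactly on the equality boundary makes the pairwise
    rank-sum sign a coin flip, which tests the noise, not the procedure).
    """
    import scipy.sparse as sp

    cm, _ = simulate_cohort(SimulationConfig(
        n_samples_per_condition=3, cells_mean=400, n_genes=120, seed=seed))
    rng = np.random.default_rng(seed)
    tumor_cells = cm.obs.index[cm.obs["cell_type"] == "tumor"]
    subclones = pd.Series(rng.choice(["C1", "C2", "C3", "C4"],
                                     size=len(tumor_cells)), index=tumor_cells)
    counts = cm.counts.toarray()
    gi = {g: i for i, g in enumerate(cm.gene_ids)}
    pos = {c: i for i, c in enumerate(cm.cell_ids)}
    c4 = [pos[c] for c in subclones.index[subclones == "C4"]]
    macro = [pos[c] for c in cm.obs.index[cm.obs["cell_type"] == "macrophage"]]
    counts[gi["G0100"], c4] += rng.poisson(20, size=len(c4))
    counts[gi["G0101"], c4] += rng.poisson(20, size=len(c4))
    counts[gi["G0101"], macro] += rng.poisson(25, size=len(macro))
    cm.counts = sp.csc_matrix(counts)

    from .markers import select_metastatic_signature

    sel = select_metastatic_signature(normalize(cm), subclones,
                                      target="C4", top_n=12)
    return {
        "planted_gene_selected": "G0100" in sel.final.genes,
        "confounded_gene_excluded": "G0101" not in sel.final.genes,
    }


# ---------------------------------------------------------------------------
# Survival power
# ---------------------------------------------------------------------------

def survival_power_rate(n_runs: int = 50, seed: int = 0,
                        hazard_log_hr: float = 0.7, n_samples: int = 300,
                        n_sig_genes: int = 10, n_boot: int = 100) -> float:
    """Fraction of synthetic cohorts whose reproducibility-power p-value is
    below 0.05 for a signature with the given log hazard ratio."""
    genes = [f"G{i:03d}" for i in range(10 * n_sig_genes)]
    sig = GeneSet("sig", genes[:n_sig_genes])
    hits = 0
    for s in _child_seeds(seed, n_runs):
        cohort = simulate_bulk_survival(n_samples, genes, sig,
                                        hazard_log_hr=hazard_log_hr,
                                        censor_rate=0.3, seed=s)
        res = survival.reproducibility_power(cohort, sig, n_boot=n_boot, seed=s)
        hits += res.power_p < 0.05
    return hits / n_runs
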