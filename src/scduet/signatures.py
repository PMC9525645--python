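"""Gene-set signature scoring at cell and sample level, plus two-group
score comparisons.

A cell's signature score is the arithmetic mean of its depth-normalized,
log-transformed expression over the genes of the set that are present in the
matrix (missing genes are logged, not zero-imputed). A sample's score is the
mean over its (optionally cell-type-restricted) cells. Two-group comparisons
use the two-sided Wilcoxon rank-sum test with the package-wide
exact/approximate policy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import rank_sum_test
from .data import GeneSet, NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = ["SignatureScores", "score_cells", "score_samples", "compare_scores",
           "compare_table"]


@dataclass
class SignatureScores:
    """Per-cell and (optionally) per-sample signature scores."""

    gene_set_name: str
    n_genes_used: int
    per_cell: pd.Series | None = None
    per_sample: pd.Series | None = None
    missing_genes: list[str] = field(default_factory=list)
    restrict_cell_type: str | None = None


def score_cells(nm: NormalizedMatrix, gs: GeneSet) -> SignatureScores:
    """Mean normalized expression over the present genes of ``gs``, per cell."""
    idx = nm.gene_index(gs.genes)
    if idx.size == 0:
        raise KeyError(
            f"no gene of set {gs.name!r} present in matrix; missing: {sorted(gs.genes)}"
        )
    present = set(nm.gene_ids[idx])
    missing = sorted(set(gs.genes) - present)
    if missing:
        log.info("signature %s: %d/%d genes absent from matrix",
                 gs.name, len(missing), len(gs))
    scores = np.asarray(nm.values[idx].mean(axis=0)).ravel()
    return SignatureScores(
        gene_set_name=gs.name,
        n_genes_used=int(idx.size),
        per_cell=pd.Series(scores, index=pd.Index(nm.cell_ids, name="cell")),
        missing_genes=missing,
    )


def score_samples(scores: SignatureScores, nm_or_cm,
                  restrict_cell_type: str | None = None) -> SignatureScores:
    """Per-sample mean of per-cell scores, optionally over one cell type only.

    Samples with no contributing cells get a missing value (logged).
    """
    obs = nm_or_cm.obs
    if "sample" not in obs:
        raise KeyError("sample metadata required for per-sample scores")
    per_cell = scores.per_cell
    mask = np.ones(len(obs), dtype=bool)
    if restrict_cell_type is not None:
        if "cell_type" not in obs:
            raise KeyError("cell_type metadata required for a restricted score")
        if restrict_cell_type not in set(obs["cell_type"].dropna()):
            raise KeyError(f"cell type {restrict_cell_type!r} not present")
        mask = (obs["cell_type"] == restrict_cell_type).to_numpy()
    grouped = per_cell[mask].groupby(obs.loc[mask, "sample"].to_numpy()).mean()
    all_samples = pd.Index(sorted(obs["sample"].dropna().unique()), name="sample")
    per_sample = grouped.reindex(all_samples)
    empty = per_sample.index[per_sample.isna()]
    if len(empty):
        log.info("signature %s: no contributing cells in samples %s",
                 scores.gene_set_name, list(empty))
    return SignatureScores(
        gene_set_name=scores.gene_set_name,
        n_genes_used=scores.n_genes_used,
        per_cell=per_cell,
        per_sample=per_sample,
        missing_genes=scores.missing_genes,
        restrict_cell_type=restrict_cell_type,
    )


def compare_scores(scores: SignatureScores, conditions: pd.Series,
                   method: str = "auto") -> tuple[float, float]:
    """Two-sided rank-sum comparison of per-sample scores between conditions.

    ``conditions`` maps sample id → condition label (exactly two labels).
    Requires ≥2 scored samples per group.
    """
    if scores.per_sample is None:
        raise ValueError("per-sample scores required; call score_samples first")
    vals = scores.per_sample.dropna()
    labels = conditions.reindex(vals.index)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 condition labels, got {groups}")
    a = vals[labels == groups[-1]]  # 'tumor' sorts after 'normal'
    b = vals[labels == groups[0]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    stat, p, policy = rank_sum_test(a, b, method=method)
    log.debug("compare_scores %s: policy=%s", scores.gene_set_name, policy)
    return stat, p


def compare_table(nm: NormalizedMatrix, gene_sets, conditions: pd.Series | None = None,
                  restrict_cell_type: str | None = None) -> pd.DataFrame:
    """Score several gene sets and tabulate their tumor-vs-normal comparisons.

    Convenience wrapper: per set → score_cells → score_samples →
    compare_scores. ``conditions`` defaults to the per-sample condition
    labels found in the metadata.
    """
    if conditions is None:
        conditions = (
            nm.obs.groupby("sample")["condition"].agg(lambda s: s.mode().iat[0])
        )
    rows = []
    for gs in gene_sets:
        sc = score_samples(score_cells(nm, gs), nm, restrict_cell_type=restrict_cell_type)
        stat, p = compare_scores(sc, conditions)
        per_group = sc.per_sample.groupby(conditions.reindex(sc.per_sample.index)).mean()
        rows.append({
            "gene_set": gs.name,
            "n_genes_used": sc.n_genes_used,
            "n_samples": int(sc.per_sample.notna().sum()),
            "mean_tumor": per_group.get("tumor", np.nan),
            "mean_normal": per_group.get("normal", np.nan),
            "statistic": stat,
            "p": p,
        })
    return pd.DataFrame(rows)
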