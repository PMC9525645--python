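"""Marker detection, pseudobulk differential expression, and the
multi-round metastatic-signature selection.

Markers are called per cluster with a one-vs-rest two-sided Wilcoxon
rank-sum test per gene; the signed Z (positive = up in the cluster) is the
normal quantile of p/2 and genes with Z above a threshold (default 3) are
flagged. Two-condition DE on pseudobulk profiles is a per-gene negative-
binomial GLM with a condition factor and a log total-count offset (Wald p,
BH adjustment) — a deliberately plain NB contract, since downstream use is
rank- and sign-based. The metastatic-signature procedure intersects two
top-N marker rounds: the target tumor subclone against the other subclones,
then the target subclone against all non-tumor populations.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial

from ._stats import bh_adjust, rank_sum_test, z_from_p
from .data import GeneSet, NormalizedMatrix
from .distance import Pseudobulk

log = logging.getLogger(__name__)

__all__ = ["marker_genes", "pseudobulk_de", "SignatureSelection",
           "select_metastatic_signature"]

_EXACT_MAX_N = 20
_CHUNK = 256


def _ranksum_z_block(values: np.ndarray, in_cluster: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-vs-rest rank-sum over a (genes × cells) block.

    Returns (z, p) per gene: tie-corrected normal approximation, Z signed by
    the rank-sum direction, with p = 2Φ(−|z|) so |Z| and p are consistent.
    """
    g, n = values.shape
    n1 = int(in_cluster.sum())
    n2 = n - n1
    ranks = stats.rankdata(values, axis=1)
    w = ranks[:, in_cluster].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    # tie correction per gene
    tie_term = np.zeros(g)
    for i in range(g):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w - mu) / np.sqrt(var)
    z = np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def marker_genes(nm: NormalizedMatrix, clusters: pd.Series | np.ndarray,
                 z_min: float = 3.0, min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers for every cluster.

    Returns a long table with columns ``cluster, gene, z, p, frac_in,
    frac_out, log2fc, is_marker``; ``z`` is signed (positive = up in the
    cluster) with |z| the normal quantile of p/2. Clusters with fewer than
    ``min_cells`` cells are skipped with a warning. For small problems
    (total cells ≤ 20) the exact per-gene rank-sum p is used.
    """
    labels = pd.Series(np.asarray(clusters), index=nm.cell_ids)
    if labels.dropna().nunique() < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    tables = []
    n = nm.n_cells
    for cl in sorted(labels.dropna().unique()):
        in_cluster = (labels == cl).to_numpy()
        if in_cluster.sum() < min_cells:
            log.warning("cluster %s has %d cells (<%d): skipped", cl,
                        in_cluster.sum(), min_cells)
            continue
        zs, ps = np.empty(nm.n_genes), np.empty(nm.n_genes)
        if n <= _EXACT_MAX_N:
            dense = nm.dense()
            for i in range(nm.n_genes):
                x, y = dense[i, in_cluster], dense[i, ~in_cluster]
                _, p, _ = rank_sum_test(x, y)
                sign = np.sign(stats.rankdata(dense[i])[in_cluster].mean()
                               - stats.rankdata(dense[i])[~in_cluster].mean())
                ps[i] = p
                zs[i] = z_from_p(p, sign if sign else 1.0) if p < 1 else 0.0
        else:
            for start in range(0, nm.n_genes, _CHUNK):
                idx = np.arange(start, min(start + _CHUNK, nm.n_genes))
                z, p = _ranksum_z_block(nm.dense(idx), in_cluster)
                zs[idx], ps[idx] = z, p
        dense_in = nm.values[:, in_cluster]
        dense_out = nm.values[:, ~in_cluster]
        mean_in = np.asarray(dense_in.mean(axis=1)).ravel()
        mean_out = np.asarray(dense_out.mean(axis=1)).ravel()
        frac_in = np.clip(np.asarray((dense_in > 0).mean(axis=1)).ravel(), 0, 1)
        frac_out = np.clip(np.asarray((dense_out > 0).mean(axis=1)).ravel(), 0, 1)
        eps = 1e-9
        tables.append(pd.DataFrame({
            "cluster": cl,
            "gene": nm.gene_ids,
            "z": zs,
            "p": ps,
            "frac_in": frac_in,
            "frac_out": frac_out,
            "log2fc": np.log2((mean_in + eps) / (mean_out + eps)),
            "is_marker": zs > z_min,
        }))
    return pd.concat(tables, ignore_index=True)


def _fit_nb(y: np.ndarray, x: np.ndarray, offset: np.ndarray):
    """NB MLE (log link, offset); Poisson GLM fallback on failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = NegativeBinomial(y, x, offset=offset).fit(disp=0, maxiter=200)
            if np.isfinite(res.params[1]) and np.isfinite(res.bse[1]) and res.bse[1] > 0:
                return res.params[1], res.bse[1]
        except Exception:  # noqa: BLE001 - any solver failure falls back
            pass
        res = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
        return res.params[1], res.bse[1]


def pseudobulk_de(pb: Pseudobulk, conditions: pd.Series, cell_type: str,
                  min_cells: int = 10) -> pd.DataFrame:
    """Tumor-vs-normal NB GLM per gene on one cell type's pseudobulk profiles.

    Model: counts ~ NB(exp(β₀ + β₁·tumor + log total)), Wald p on β₁,
    ``log2FoldChange = β₁ / ln 2`` (tumor vs normal), BH adjustment.
    Requires ≥2 samples per condition passing ``min_cells``.
    """
    sel = pb.profiles.xs(cell_type, level="cell_type")
    n_cells = pb.n_cells.xs(cell_type, level="cell_type")
    sel = sel.loc[n_cells[n_cells >= min_cells].index]
    cond = conditions.reindex(sel.index)
    is_tumor = (cond == "tumor").to_numpy().astype(float)
    if is_tumor.sum() < 2 or (1 - is_tumor).sum() < 2:
        raise ValueError(
            f"cell type {cell_type!r}: need >=2 samples per condition with "
            f">={min_cells} cells"
        )
    y_all = sel.to_numpy(float)
    offset = np.log(y_all.sum(axis=1))
    x = np.column_stack([np.ones_like(is_tumor), is_tumor])
    ln2 = np.log(2.0)
    rows = []
    for gi, gene in enumerate(sel.columns):
        y = y_all[:, gi]
        if y.sum() == 0:
            rows.append({"gene": gene, "log2FoldChange": 0.0, "p": np.nan})
            continue
        beta, se = _fit_nb(y, x, offset)
        wald = beta / se
        rows.append({"gene": gene, "log2FoldChange": beta / ln2,
                     "p": 2.0 * stats.norm.sf(abs(wald))})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    out.attrs["contrast"] = "tumor_vs_normal"
    out.attrs["cell_type"] = cell_type
    out.attrs["samples"] = list(sel.index)
    return out


@dataclass
class SignatureSelection:
    """Two-round top-N marker selection for the metastasis-associated subclone."""

    round1_top: list[str]
    round2_top: list[str]
    final: GeneSet


def _top_positive(table: pd.DataFrame, cluster: str, top_n: int) -> list[str]:
    sub = table[(table["cluster"] == cluster) & (table["z"] > 0)].copy()
    # rank by Z desc, tie-break |log2FC| desc then symbol
    sub = sub.sort_values(["z", "log2fc", "gene"],
                          ascending=[False, False, True],
                          key=lambda s: s.abs() if s.name == "log2fc" else s)
    return sub["gene"].head(top_n).tolist()


def select_metastatic_signature(nm: NormalizedMatrix, subclones: pd.Series,
                                target: str = "C4", top_n: int = 100,
                                min_target_cells: int = 50) -> SignatureSelection:
    """Intersect two marker rounds to nominate metastasis-associated genes.

    Round 1: one-vs-rest markers of the ``target`` subclone among the tumor
    subclones (``subclones``: subclone label per tumor cell barcode),
    positive Z, top ``top_n`` by rank. Round 2: specificity against the
    non-tumor cell populations (cells absent from ``subclones``, grouped by
    their ``cell_type``) — a gene must be up in the target versus every
    population pairwise, and genes are ranked by their minimum pairwise Z,
    so a gene shared with any single population is excluded. Final =
    round-1 ∩ round-2, ordered by round-1 rank; an empty intersection is a
    valid (warned) outcome.
    """
    subclones = subclones.dropna()
    target_cells = subclones.index[subclones == target]
    if len(target_cells) < min_target_cells:
        raise ValueError(
            f"target subclone {target!r} has {len(target_cells)} cells "
            f"(<{min_target_cells})"
        )
    cell_pos = {c: i for i, c in enumerate(nm.cell_ids)}

    # Round 1: target vs other subclones, within tumor cells.
    tumor_idx = np.array([cell_pos[c] for c in subclones.index])
    nm_tumor = _subset_nm(nm, tumor_idx)
    round1 = marker_genes(nm_tumor, subclones.to_numpy(), z_min=0.0)
    round1_top = _top_positive(round1, target, top_n)

    # Round 2: specificity — the target subclone must beat EVERY non-tumor
    # population pairwise; genes are ranked by their worst (minimum) Z.
    non_tumor = nm.obs.index[~nm.obs.index.isin(subclones.index)]
    non_tumor_types = nm.obs.loc[non_tumor, "cell_type"].dropna()
    if non_tumor_types.nunique() < 2:
        raise ValueError("need at least 2 non-tumor cell populations")
    target_idx = np.array([cell_pos[c] for c in target_cells])
    min_z = np.full(nm.n_genes, np.inf)
    for pop in sorted(non_tumor_types.unique()):
        pop_idx = np.array([cell_pos[c] for c in non_tumor_types.index[non_tumor_types == pop]])
        both = np.concatenate([target_idx, pop_idx])
        in_target = np.zeros(both.size, dtype=bool)
        in_target[: target_idx.size] = True
        for start in range(0, nm.n_genes, _CHUNK):
            gidx = np.arange(start, min(start + _CHUNK, nm.n_genes))
            z, _ = _ranksum_z_block(nm.dense(gidx)[:, both], in_target)
            min_z[gidx] = np.minimum(min_z[gidx], z)
    order = np.lexsort((nm.gene_ids.astype(str), -min_z))
    round2_top = [nm.gene_ids[i] for i in order if min_z[i] > 0][:top_n]

    final = [g for g in round1_top if g in set(round2_top)]
    if not final:
        log.warning("metastatic-signature selection: empty intersection")
    return SignatureSelection(
        round1_top=round1_top,
        round2_top=round2_top,
        final=GeneSet("metastatic_signature", final),
    )


def _subset_nm(nm: NormalizedMatrix, idx: np.ndarray) -> NormalizedMatrix:
    return NormalizedMatrix(
        values=nm.values[:, idx],
        gene_ids=nm.gene_ids,
        cell_ids=nm.cell_ids[idx],
        obs=nm.obs.iloc[idx],
        embedding=None if nm.embedding is None else nm.embedding[idx],
        provenance=nm.provenance,
    )
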