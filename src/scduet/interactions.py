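"""Ligand-receptor interaction inference between annotated cell types.

A candidate (pair, sender, receiver) triple scores as the product of the
mean normalized ligand expression over sender cells and the mean receptor
expression over receiver cells. Candidates require each gene expressed in
more than a minimum fraction of its cell type (default 10%, strict). The
null is built by shuffling cell-type labels globally (cell-type sizes
preserved) and rescoring over permutations; p-values are add-one estimates
with BH adjustment across all triples. Two further filters mirror the
biology: cell-type specificity (marker Z of ligand in sender and receptor in
receiver above a threshold) and tumor upregulation (pseudobulk log2FC > 0).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .data import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "LRPairTable",
    "read_lr_pairs",
    "screen_pairs",
    "score_pairs",
    "permutation_test",
    "specificity_filter",
    "condition_filter",
    "expression_dotplot_table",
]


@dataclass
class LRPairTable:
    """Candidate ligand-receptor pairs (unique pair ids)."""

    pairs: pd.DataFrame  # columns: ligand, receptor, pair_id

    def __post_init__(self):
        req = {"ligand", "receptor", "pair_id"}
        if not req <= set(self.pairs.columns):
            raise ValueError(f"pair table needs columns {sorted(req)}")
        if self.pairs["pair_id"].duplicated().any():
            raise ValueError("duplicate pair ids")
        if (self.pairs[["ligand", "receptor"]] == "").any().any():
            raise ValueError("empty gene symbol in pair table")


def read_lr_pairs(path) -> LRPairTable:
    """Read a CellPhoneDB-style two-column TSV (ligand, receptor[, id])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "ligand" not in cols or "receptor" not in cols:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        df.columns = ["ligand", "receptor"] + [f"c{i}" for i in range(df.shape[1] - 2)]
    if "pair_id" not in df.columns:
        df["pair_id"] = df["ligand"] + "_" + df["receptor"]
    return LRPairTable(df[["ligand", "receptor", "pair_id"]].copy())


def _type_stats(nm: NormalizedMatrix, genes: list[str]):
    """Per cell type: mean expression and expressing fraction of the genes."""
    idx = nm.gene_index(genes)
    present = list(nm.gene_ids[idx])
    dense = nm.dense(idx)
    types = nm.obs["cell_type"]
    means, fracs = {}, {}
    for ct in sorted(types.dropna().unique()):
        m = (types == ct).to_numpy()
        means[ct] = pd.Series(dense[:, m].mean(axis=1), index=present)
        fracs[ct] = pd.Series((dense[:, m] > 0).mean(axis=1), index=present)
    return means, fracs, present


def screen_pairs(nm: NormalizedMatrix, pairs: LRPairTable,
                 min_frac: float = 0.10) -> pd.DataFrame:
    """Candidate (pair, sender, receiver) triples.

    A triple is kept when the ligand is expressed (count > 0) in strictly
    more than ``min_frac`` of sender cells AND the receptor in more than
    ``min_frac`` of receiver cells. Pairs with a gene absent from the matrix
    are dropped (logged).
    """
    if "cell_type" not in nm.obs:
        raise ValueError("cell_type annotation required")
    genes = sorted(set(pairs.pairs["ligand"]) | set(pairs.pairs["receptor"]))
    _, fracs, present = _type_stats(nm, genes)
    present_set = set(present)
    dropped = pairs.pairs[~(pairs.pairs["ligand"].isin(present_set)
                            & pairs.pairs["receptor"].isin(present_set))]
    if len(dropped):
        log.info("dropping %d pairs with genes absent from matrix", len(dropped))
    usable = pairs.pairs.drop(dropped.index)
    types = sorted(fracs)
    rows = []
    for _, pair in usable.iterrows():
        for sender in types:
            if fracs[sender][pair["ligand"]] <= min_frac:
                continue
            for receiver in types:
                if fracs[receiver][pair["receptor"]] <= min_frac:
                    continue
                rows.append({"pair_id": pair["pair_id"], "ligand": pair["ligand"],
                             "receptor": pair["receptor"], "sender": sender,
                             "receiver": receiver})
    return pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor",
                                       "sender", "receiver"])


def score_pairs(nm: NormalizedMatrix, candidates: pd.DataFrame) -> pd.DataFrame:
    """Score = mean ligand expression in sender × mean receptor in receiver."""
    out = candidates.copy()
    genes = sorted(set(out["ligand"]) | set(out["receptor"]))
    means, _, _ = _type_stats(nm, genes)
    out["score"] = [
        means[r["sender"]][r["ligand"]] * means[r["receiver"]][r["receptor"]]
        for _, r in out.iterrows()
    ]
    return out


def permutation_test(nm: NormalizedMatrix, candidates: pd.DataFrame,
                     n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Permutation p per triple: cell-type labels shuffled globally.

    p = (1 + #{permuted score ≥ observed}) / (1 + n_perm), compared per
    triple; BH adjustment across all triples.
    """
    if "score" not in candidates:
        candidates = score_pairs(nm, candidates)
    out = candidates.copy().reset_index(drop=True)
    genes = sorted(set(out["ligand"]) | set(out["receptor"]))
    idx = nm.gene_index(genes)
    present = list(nm.gene_ids[idx])
    dense = nm.dense(idx)  # genes x cells
    gpos = {g: i for i, g in enumerate(present)}
    types = nm.obs["cell_type"].to_numpy()
    type_names = sorted(pd.unique(types[pd.notna(types)]))
    tpos = {t: i for i, t in enumerate(type_names)}
    onehot = np.zeros((dense.shape[1], len(type_names)))
    for t, i in tpos.items():
        onehot[types == t, i] = 1.0
    onehot /= onehot.sum(axis=0, keepdims=True)

    li = out["ligand"].map(gpos).to_numpy()
    ri = out["receptor"].map(gpos).to_numpy()
    si = out["sender"].map(tpos).to_numpy()
    vi = out["receiver"].map(tpos).to_numpy()
    obs = out["score"].to_numpy()

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(out), dtype=int)
    n_cells = dense.shape[1]
    for _ in range(n_perm):
        perm = rng.permutation(n_cells)
        means = dense[:, perm] @ onehot  # genes x types
        perm_scores = means[li, si] * means[ri, vi]
        exceed += perm_scores >= obs - 1e-12
    out["p"] = (1 + exceed) / (1 + n_perm)
    out["p_adj"] = bh_adjust(out["p"])
    return out


def specificity_filter(marker_table: pd.DataFrame, candidates: pd.DataFrame,
                       z_min: float = 3.0) -> pd.DataFrame:
    """Keep triples whose ligand is a sender marker and receptor a receiver
    marker (one-vs-rest Z ≥ ``z_min`` for both)."""
    z = marker_table.set_index(["cluster", "gene"])["z"]

    def _z(cluster, gene):
        return z.get((cluster, gene), -np.inf)

    out = candidates.copy()
    out["ligand_specificity_z"] = [
        _z(r["sender"], r["ligand"]) for _, r in out.iterrows()
    ]
    out["receptor_specificity_z"] = [
        _z(r["receiver"], r["receptor"]) for _, r in out.iterrows()
    ]
    keep = ((out["ligand_specificity_z"] >= z_min)
            & (out["receptor_specificity_z"] >= z_min))
    return out[keep].reset_index(drop=True)


def condition_filter(de_tables: dict[str, pd.DataFrame], candidates: pd.DataFrame,
                     mode: str = "both") -> pd.DataFrame:
    """Keep triples upregulated in tumor (strict log2FC > 0).

    ``mode="both"`` requires the ligand (in the sender's tumor-vs-normal DE
    table) and the receptor (in the receiver's) both up; ``mode="either"``
    requires at least one. Triples involving a type without a DE table are
    dropped (warned).
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    lfc = {t: df.set_index("gene")["log2FoldChange"] for t, df in de_tables.items()}
    rows = []
    n_missing = 0
    for _, r in candidates.iterrows():
        if r["sender"] not in lfc or r["receiver"] not in lfc:
            n_missing += 1
            continue
        lig = lfc[r["sender"]].get(r["ligand"], np.nan)
        rec = lfc[r["receiver"]].get(r["receptor"], np.nan)
        up_l, up_r = lig > 0, rec > 0
        keep = (up_l and up_r) if mode == "both" else (up_l or up_r)
        if keep:
            row = dict(r)
            row["ligand_log2fc"], row["receptor_log2fc"] = lig, rec
            rows.append(row)
    if n_missing:
        log.warning("%d triples dropped: missing DE table for their types", n_missing)
    cols = list(candidates.columns) + ["ligand_log2fc", "receptor_log2fc"]
    return pd.DataFrame(rows, columns=cols)


def expression_dotplot_table(nm: NormalizedMatrix, genes: list[str]) -> pd.DataFrame:
    """Long table (gene, cell_type, mean_expression, fraction_expressing) for
    dot-plot style summaries of candidate ligands/receptors."""
    means, fracs, present = _type_stats(nm, genes)
    rows = [
        {"gene": g, "cell_type": ct, "mean_expression": means[ct][g],
         "fraction_expressing": fracs[ct][g]}
        for ct in means for g in present
    ]
    return pd.DataFrame(rows)
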