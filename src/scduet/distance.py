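"""Pseudobulk construction and expression-distance statistics.

Per-(sample, cell-type) "mini-bulk" profiles are formed by summing the
molecules of all member cells. The distance between two profiles is
1 − Pearson correlation of depth-normalized, log1p-transformed values over
the genes expressed in at least one of the pair. The per-cell-type
normalized distance is the median between-condition pair distance divided by
the median within-condition pair distance (≈1 under no condition effect),
averaged over cell-subsampling rounds that equalize cell numbers; its
significance comes from permuting sample condition labels. Overall
sample-to-sample distances are proportion-weighted sums across cell types,
projected to 2-D with classical (Torgerson) MDS.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CellMatrix

log = logging.getLogger(__name__)

__all__ = [
    "Pseudobulk",
    "DistanceResult",
    "SampleMap",
    "make_pseudobulk",
    "pair_distance",
    "celltype_distance",
    "distance_permutation_test",
    "overall_sample_distance",
    "classical_mds",
]


@dataclass
class Pseudobulk:
    """Summed counts per (sample, cell type) with per-profile cell counts."""

    profiles: pd.DataFrame       # (sample, cell_type) MultiIndex x genes
    n_cells: pd.Series           # per profile
    proportions: pd.Series       # per (sample, cell_type), over ALL typed cells
    min_cells: int

    @property
    def samples(self) -> list[str]:
        return sorted(self.profiles.index.get_level_values("sample").unique())

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.profiles.index.get_level_values("cell_type").unique())


def make_pseudobulk(cm: CellMatrix, min_cells: int = 10) -> Pseudobulk:
    """Sum counts per (sample, cell type); profiles under ``min_cells`` cells
    are excluded (logged). Proportions are over all typed cells per sample."""
    obs = cm.obs.dropna(subset=["cell_type", "sample"])
    groups = obs.groupby(["sample", "cell_type"], observed=True).indices
    sizes = pd.Series({k: len(v) for k, v in groups.items()})
    sizes.index = pd.MultiIndex.from_tuples(sizes.index, names=["sample", "cell_type"])
    sample_totals = sizes.groupby(level="sample").sum()
    proportions = sizes / sample_totals.reindex(sizes.index.get_level_values("sample")).to_numpy()

    kept, rows = [], []
    csc = sp.csc_matrix(cm.counts)
    pos = {c: i for i, c in enumerate(cm.cell_ids)}
    for key, cells in groups.items():
        if len(cells) < min_cells:
            log.info("pseudobulk profile %s excluded (%d < %d cells)",
                     key, len(cells), min_cells)
            continue
        idx = [pos[obs.index[i]] for i in cells]
        rows.append(np.asarray(csc[:, idx].sum(axis=1)).ravel())
        kept.append(key)
    profiles = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(kept, names=["sample", "cell_type"]),
        columns=cm.gene_ids,
    )
    return Pseudobulk(profiles=profiles, n_cells=sizes.loc[kept],
                      proportions=proportions, min_cells=min_cells)


def pair_distance(profile_a, profile_b, normalize: bool = True,
                  log_transform: bool = True) -> float:
    """1 − Pearson correlation of (depth-normalized, log1p) profiles over the
    genes with a nonzero count in at least one of the pair."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    expressed = (a > 0) | (b > 0)
    a, b = a[expressed], b[expressed]
    if normalize:
        a = a / a.sum() * 1e6
        b = b / b.sum() * 1e6
    if log_transform:
        a, b = np.log1p(a), np.log1p(b)
    tol = 1e-10
    if a.std() <= tol * (np.abs(a).max() + 1) or b.std() <= tol * (np.abs(b).max() + 1):
        raise ValueError("zero-variance profile: correlation undefined")
    return float(1.0 - np.corrcoef(a, b)[0, 1])


@dataclass
class DistanceResult:
    """Per-cell-type normalized expression distances with cached pairwise
    distance matrices (sample × sample, subsampling-averaged) so label
    permutations can be evaluated without re-sampling cells."""

    normalized_distance: pd.Series
    distances: dict[str, pd.DataFrame]
    conditions: pd.Series
    n_rounds: int
    permutation_p: pd.Series | None = None
    skipped: list[str] = field(default_factory=list)


def _normalized_stat(dmat: np.ndarray, is_tumor: np.ndarray) -> float:
    between, within = [], []
    n = len(is_tumor)
    for i, j in combinations(range(n), 2):
        (between if is_tumor[i] != is_tumor[j] else within).append(dmat[i, j])
    return float(np.median(between) / np.median(within))


def celltype_distance(cm: CellMatrix, min_cells: int = 10, n_rounds: int = 100,
                      seed: int | None = None,
                      cell_types: list[str] | None = None) -> DistanceResult:
    """Per-type normalized expression distance between conditions.

    For each cell type, contributing samples are those with ≥ ``min_cells``
    cells of the type (≥2 per condition required; types present in only one
    condition are skipped with a warning). Each round subsamples every
    contributing sample to the minimum cell count among them (without
    replacement), rebuilds the profiles, and accumulates all pairwise
    distances; distances are averaged over rounds before the
    between/within-median ratio is taken.
    """
    cm.require_conditions()
    rng = np.random.default_rng(seed)
    obs = cm.obs.dropna(subset=["cell_type", "sample"])
    sample_cond = obs.groupby("sample")["condition"].agg(lambda s: s.mode().iat[0])
    csc = sp.csc_matrix(cm.counts)
    pos = {c: i for i, c in enumerate(cm.cell_ids)}

    types = cell_types or sorted(obs["cell_type"].unique())
    norm_dist, dmats, skipped = {}, {}, []
    for ct in types:
        cells_by_sample = {
            s: [pos[c] for c in grp.index]
            for s, grp in obs[obs["cell_type"] == ct].groupby("sample")
        }
        contributing = {s: v for s, v in cells_by_sample.items() if len(v) >= min_cells}
        conds = sample_cond.reindex(list(contributing))
        if len(set(conds)) < 2 or (conds == "tumor").sum() < 2 or (conds == "normal").sum() < 2:
            log.warning("cell type %s: insufficient samples per condition, skipped", ct)
            skipped.append(ct)
            continue
        samples = sorted(contributing)
        m = min(len(contributing[s]) for s in samples)
        acc = np.zeros((len(samples), len(samples)))
        for _ in range(n_rounds):
            profs = []
            for s in samples:
                idx = contributing[s]
                take = idx if len(idx) == m else rng.choice(idx, size=m, replace=False)
                profs.append(np.asarray(csc[:, list(take)].sum(axis=1)).ravel())
            for i, j in combinations(range(len(samples)), 2):
                d = pair_distance(profs[i], profs[j])
                acc[i, j] += d
                acc[j, i] += d
        acc /= n_rounds
        dmats[ct] = pd.DataFrame(acc, index=samples, columns=samples)
        norm_dist[ct] = _normalized_stat(acc, (conds == "tumor").to_numpy())
    return DistanceResult(
        normalized_distance=pd.Series(norm_dist, name="normalized_distance"),
        distances=dmats, conditions=sample_cond, n_rounds=n_rounds, skipped=skipped,
    )


def distance_permutation_test(result: DistanceResult, n_perm: int = 1000,
                              seed: int | None = None) -> pd.Series:
    """Permutation p per cell type: condition labels permuted at sample level.

    p = (1 + #{permuted statistic ≥ observed}) / (1 + n_perm); when fewer
    than 20 distinct label assignments exist, exact enumeration over all
    assignments is used instead (logged).
    """
    rng = np.random.default_rng(seed)
    ps = {}
    for ct, dmat in result.distances.items():
        samples = list(dmat.index)
        is_tumor = (result.conditions.reindex(samples) == "tumor").to_numpy()
        obs = result.normalized_distance[ct]
        arr = dmat.to_numpy()
        n, k = len(samples), int(is_tumor.sum())
        if comb(n, k) < 20:
            log.info("cell type %s: exact enumeration over %d label splits", ct, comb(n, k))
            hits = total = 0
            for idx in combinations(range(n), k):
                lab = np.zeros(n, dtype=bool)
                lab[list(idx)] = True
                total += 1
                if _normalized_stat(arr, lab) >= obs - 1e-12:
                    hits += 1
            ps[ct] = hits / total
        else:
            hits = 0
            for _ in range(n_perm):
                lab = np.zeros(n, dtype=bool)
                lab[rng.choice(n, size=k, replace=False)] = True
                if _normalized_stat(arr, lab) >= obs - 1e-12:
                    hits += 1
            ps[ct] = (1 + hits) / (1 + n_perm)
    out = pd.Series(ps, name="permutation_p")
    result.permutation_p = out
    return out


@dataclass
class SampleMap:
    """Symmetric sample × sample distance matrix with 2-D MDS coordinates."""

    distance_matrix: pd.DataFrame
    mds_coords: pd.DataFrame


def classical_mds(dmat: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: double-center −D²/2 and take the top-k
    eigenvectors scaled by the root eigenvalues."""
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dmat ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def overall_sample_distance(pb: Pseudobulk) -> SampleMap:
    """Proportion-weighted overall distance between samples.

    d(s,t) = Σₖ wₖ·dₖ(s,t) / Σₖ wₖ with wₖ = min(proportion of type k in s,
    in t), over cell types passing the pseudobulk cell minimum in both
    samples. Pairs sharing no type get the matrix maximum imputed (logged).
    """
    samples = pb.samples
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    dmat = np.zeros((len(samples), len(samples)))
    missing = []
    for i, j in combinations(range(len(samples)), 2):
        s, t = samples[i], samples[j]
        num = den = 0.0
        for ct in pb.cell_types:
            if (s, ct) not in pb.profiles.index or (t, ct) not in pb.profiles.index:
                continue
            w = min(pb.proportions.get((s, ct), 0.0), pb.proportions.get((t, ct), 0.0))
            if w <= 0:
                continue
            num += w * pair_distance(pb.profiles.loc[(s, ct)], pb.profiles.loc[(t, ct)])
            den += w
        if den == 0:
            missing.append((i, j))
        else:
            dmat[i, j] = dmat[j, i] = num / den
    if missing:
        fill = dmat.max()
        log.warning("%d sample pairs share no cell type; distance imputed as %.4g",
                    len(missing), fill)
        for i, j in missing:
            dmat[i, j] = dmat[j, i] = fill
    coords = classical_mds(dmat, k=2)
    return SampleMap(
        distance_matrix=pd.DataFrame(dmat, index=samples, columns=samples),
        mds_coords=pd.DataFrame(coords, index=samples, columns=["MDS1", "MDS2"]),
    )
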