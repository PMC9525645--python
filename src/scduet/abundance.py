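"""Differential cell abundance: kernel density maps on a shared embedding,
direct cell-type proportion tests, and compositional data analysis (CoDA).

Density analysis estimates a per-sample Gaussian kernel density on a shared
grid over the joint 2-D embedding, quantile-normalizes the per-sample
density vectors, and compares conditions bin-wise with a Welch t statistic
reported as a signed Z (positive = denser in tumor). Compositional analysis
maps per-sample cell-type fractions through an isometric log-ratio (ILR)
transform, finds the canonical discriminant axis separating tumor from
normal, and reports per-type separating coefficients in CLR space with a
bootstrap (samples and cells) for uncertainty.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert
from skbio.stats.composition import clr

from ._stats import bh_adjust, rank_sum_test, z_from_p
from .data import CellMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DensityGrid",
    "DensityDiffMap",
    "CompositionResult",
    "estimate_density",
    "quantile_normalize_grids",
    "density_diff",
    "celltype_fractions",
    "proportion_tests",
    "coda_coefficients",
]


# ---------------------------------------------------------------------------
# Kernel density on the shared embedding
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Per-sample kernel densities on a shared G × G grid."""

    grids: dict[str, np.ndarray]          # sample -> (G, G) density
    extent: tuple[float, float, float, float]
    gridsize: int
    bandwidths: dict[str, np.ndarray]     # sample -> 2x2 kernel covariance
    cell_counts: np.ndarray               # (G, G) occupancy over all cells
    conditions: dict[str, str]

    @property
    def bin_area(self) -> float:
        x0, x1, y0, y1 = self.extent
        return ((x1 - x0) / self.gridsize) * ((y1 - y0) / self.gridsize)


@dataclass
class DensityDiffMap:
    """Signed per-bin Z map (positive = denser in tumor) with occupancy mask."""

    z: np.ndarray
    mask: np.ndarray


def estimate_density(cm: CellMatrix, gridsize: int = 400, min_cells: int = 10,
                     margin: float = 0.05) -> DensityGrid:
    """Per-sample Gaussian KDE (Scott-type plug-in bandwidth) on a shared grid.

    The bounding box is computed over all samples and padded by ``margin``;
    each sample's density is renormalized so density × bin area sums to 1.
    Samples with fewer than ``min_cells`` cells are excluded with a warning.
    """
    if cm.embedding is None:
        raise ValueError("embedding coordinates required for density estimation")
    xy = cm.embedding
    x0, x1 = xy[:, 0].min(), xy[:, 0].max()
    y0, y1 = xy[:, 1].min(), xy[:, 1].max()
    dx, dy = margin * (x1 - x0), margin * (y1 - y0)
    extent = (x0 - dx, x1 + dx, y0 - dy, y1 + dy)

    gx = np.linspace(extent[0], extent[1], gridsize)
    gy = np.linspace(extent[2], extent[3], gridsize)
    mesh = np.vstack([m.ravel() for m in np.meshgrid(gx, gy, indexing="ij")])

    grids, bandwidths, conditions = {}, {}, {}
    samples = cm.obs["sample"]
    for sample in sorted(samples.dropna().unique()):
        pts = xy[(samples == sample).to_numpy()]
        if len(pts) < min_cells:
            log.warning("sample %s has %d cells (<%d): excluded from density",
                        sample, len(pts), min_cells)
            continue
        kde = stats.gaussian_kde(pts.T)  # Scott's rule by default
        dens = kde(mesh).reshape(gridsize, gridsize)
        bin_area = ((extent[1] - extent[0]) / gridsize) * ((extent[3] - extent[2]) / gridsize)
        dens /= dens.sum() * bin_area
        grids[sample] = dens
        bandwidths[sample] = kde.covariance.copy()
        if "condition" in cm.obs:
            in_sample = (samples == sample).to_numpy()
            conditions[sample] = cm.obs.loc[in_sample, "condition"].mode().iat[0]

    counts, _, _ = np.histogram2d(
        xy[:, 0], xy[:, 1],
        bins=[np.linspace(extent[0], extent[1], gridsize + 1),
              np.linspace(extent[2], extent[3], gridsize + 1)],
    )
    return DensityGrid(grids=grids, extent=extent, gridsize=gridsize,
                       bandwidths=bandwidths, cell_counts=counts,
                       conditions=conditions)


def quantile_normalize_grids(dg: DensityGrid) -> DensityGrid:
    """Quantile-normalize the per-sample density vectors.

    After normalization every sample's sorted value vector equals the mean of
    the input sorted vectors; ties within a sample map to the mean of their
    tied reference quantiles (rank-preserving within sample).
    """
    samples = list(dg.grids)
    if len(samples) < 2:
        raise ValueError("quantile normalization needs at least 2 grids")
    shape = dg.grids[samples[0]].shape
    mat = np.stack([dg.grids[s].ravel() for s in samples], axis=1)
    if any(dg.grids[s].shape != shape for s in samples):
        raise ValueError("grid shape mismatch")
    ref = np.sort(mat, axis=0).mean(axis=1)
    n = mat.shape[0]
    out = {}
    for j, s in enumerate(samples):
        ranks = stats.rankdata(mat[:, j], method="average")
        vals = np.interp(ranks, np.arange(1, n + 1), ref)
        out[s] = vals.reshape(shape)
    return DensityGrid(grids=out, extent=dg.extent, gridsize=dg.gridsize,
                       bandwidths=dg.bandwidths, cell_counts=dg.cell_counts,
                       conditions=dg.conditions)


def density_diff(dg: DensityGrid, conditions: dict[str, str] | None = None,
                 min_cells_per_bin: int = 1) -> DensityDiffMap:
    """Per-bin Welch t between tumor and normal sample densities, as signed Z.

    Positive Z = denser in tumor. Bins with fewer than ``min_cells_per_bin``
    cells across all samples are masked (Z forced to 0); bins with zero
    variance in both groups and equal means give Z = 0.
    """
    conditions = conditions or dg.conditions
    tumor = [dg.grids[s] for s in dg.grids if conditions[s] == "tumor"]
    normal = [dg.grids[s] for s in dg.grids if conditions[s] == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need at least 2 samples per condition")
    a, b = np.stack(tumor), np.stack(normal)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical columns trigger a benign precision warning in scipy
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    z = z_from_p(np.nan_to_num(p, nan=1.0), sign=1.0) * np.sign(np.nan_to_num(t))
    # zero variance in both groups: equal means -> 0 (nan t), unequal -> +/- inf t
    degenerate = ~np.isfinite(t) & np.isclose(a.mean(axis=0), b.mean(axis=0))
    z[degenerate] = 0.0
    z[~np.isfinite(t) & ~degenerate] = np.sign(
        (a.mean(axis=0) - b.mean(axis=0))[~np.isfinite(t) & ~degenerate]
    ) * z_from_p(0.0)
    mask = dg.cell_counts >= min_cells_per_bin
    z = np.where(mask, z, 0.0)
    return DensityDiffMap(z=z, mask=mask)


# ---------------------------------------------------------------------------
# Direct proportion tests
# ---------------------------------------------------------------------------

def celltype_fractions(cm: CellMatrix, denominator: str = "all",
                       parent_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-sample cell-type fractions (samples × types).

    ``denominator="all"`` divides by the sample's total cells;
    ``denominator="parent"`` divides each type's count by the sample's count
    of cells in the same parent compartment (``parent_map``: type → parent),
    e.g. myeloid subsets over total myeloid cells. Zero denominators give
    missing values (logged).
    """
    obs = cm.obs.dropna(subset=["cell_type"])
    dropped = cm.n_cells - len(obs)
    if dropped:
        log.info("excluding %d cells without a cell_type label", dropped)
    counts = obs.groupby(["sample", "cell_type"]).size().unstack(fill_value=0)
    if denominator == "all":
        denom = counts.sum(axis=1)
        fractions = counts.div(denom, axis=0)
    elif denominator == "parent":
        if parent_map is None:
            raise ValueError("parent_map required for denominator='parent'")
        fractions = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
        for ct in counts.columns:
            siblings = [c for c in counts.columns
                        if parent_map.get(c) == parent_map.get(ct)]
            denom = counts[siblings].sum(axis=1)
            zero = denom == 0
            if zero.any():
                log.info("type %s: zero parent denominator in samples %s",
                         ct, list(counts.index[zero]))
            fractions[ct] = counts[ct] / denom.replace(0, np.nan)
    else:
        raise ValueError("denominator must be 'all' or 'parent'")
    return fractions


def proportion_tests(cm: CellMatrix, denominator: str = "all",
                     parent_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-cell-type two-sided rank-sum test of tumor vs normal fractions,
    with a BH-adjusted column."""
    cm.require_conditions()
    fractions = celltype_fractions(cm, denominator=denominator, parent_map=parent_map)
    cond = cm.obs.groupby("sample")["condition"].agg(lambda s: s.mode().iat[0])
    cond = cond.reindex(fractions.index)
    rows = []
    for ct in fractions.columns:
        f = fractions[ct].dropna()
        a = f[cond.reindex(f.index) == "tumor"]
        b = f[cond.reindex(f.index) == "normal"]
        if len(a) < 2 or len(b) < 2:
            rows.append({"cell_type": ct, "statistic": np.nan, "p": np.nan,
                         "mean_tumor": a.mean(), "mean_normal": b.mean()})
            continue
        stat, p, _ = rank_sum_test(a, b)
        rows.append({"cell_type": ct, "statistic": stat, "p": p,
                     "mean_tumor": a.mean(), "mean_normal": b.mean()})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out


# ---------------------------------------------------------------------------
# Compositional data analysis
# ---------------------------------------------------------------------------

@dataclass
class CompositionResult:
    """Per-type separating coefficients in CLR space with bootstrap draws.

    Positive coefficient = enriched in tumor. Coefficients sum to ~0 (CLR
    zero-sum) and are invariant to the ILR basis choice.
    """

    coefficients: pd.Series
    bootstrap_draws: pd.DataFrame

    def quantiles(self, qs=(0.025, 0.25, 0.5, 0.75, 0.975)) -> pd.DataFrame:
        return self.bootstrap_draws.quantile(list(qs)).T


def _close_fractions(counts: np.ndarray) -> np.ndarray:
    """Multiplicative zero replacement (half-cell pseudo-count) and closure."""
    x = counts.astype(float)
    x[x == 0] = 0.5
    return x / x.sum(axis=1, keepdims=True)


def _discriminant_clr(fracs: np.ndarray, is_tumor: np.ndarray,
                      basis: np.ndarray) -> np.ndarray:
    """Two-group canonical discriminant axis in ILR space, mapped to CLR.

    The axis is w = S_w⁺ (m₁ − m₀) with pooled within-class scatter S_w,
    oriented so the tumor mean projects positive, and mapped back through
    the orthonormal basis (CLR coefficients are basis-invariant).
    """
    coords = clr(fracs) @ basis.T
    m1, m0 = coords[is_tumor].mean(axis=0), coords[~is_tumor].mean(axis=0)
    centered = np.where(is_tumor[:, None], coords - m1, coords - m0)
    sw = centered.T @ centered / max(len(coords) - 2, 1)
    w = np.linalg.pinv(sw) @ (m1 - m0)
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    if (m1 - m0) @ w < 0:
        w = -w
    return basis.T @ w


def ilr_basis(d: int) -> np.ndarray:
    """Orthonormal Helmert-type ILR contrast matrix, shape (d-1, d)."""
    return helmert(d, full=False)


def coda_coefficients(counts: pd.DataFrame, conditions: pd.Series,
                      n_boot: int = 1000, cells_per_boot: int = 1000,
                      seed: int | None = None,
                      basis: np.ndarray | None = None) -> CompositionResult:
    """Separating coefficients between tumor and normal compositions.

    ``counts``: samples × cell-types table of cell counts. Zero fractions are
    replaced by half a cell before closure. Bootstrap rounds resample samples
    with replacement within each condition, then draw ``cells_per_boot``
    cells per condition (allocated across the drawn samples proportionally to
    their cell counts, without replacement within a sample).
    """
    keep = counts.columns[counts.sum(axis=0) > 0]
    dropped = set(counts.columns) - set(keep)
    if dropped:
        log.warning("cell types absent from every sample dropped: %s", sorted(dropped))
    counts = counts[keep]
    cond = conditions.reindex(counts.index)
    is_tumor = (cond == "tumor").to_numpy()
    if is_tumor.sum() < 3 or (~is_tumor).sum() < 3:
        raise ValueError("need at least 3 samples per condition")
    d = counts.shape[1]
    if basis is None:
        basis = ilr_basis(d)

    coef = _discriminant_clr(_close_fractions(counts.to_numpy()), is_tumor, basis)
    rng = np.random.default_rng(seed)
    groups = {True: np.where(is_tumor)[0], False: np.where(~is_tumor)[0]}
    raw = counts.to_numpy(int)
    draws = np.empty((n_boot, d))
    for b in range(n_boot):
        rows, labels = [], []
        for tumor_flag, idx in groups.items():
            pick = rng.choice(idx, size=len(idx), replace=True)
            totals = raw[pick].sum(axis=1)
            alloc = rng.multinomial(cells_per_boot, totals / totals.sum())
            for i, n_draw in zip(pick, alloc):
                n_draw = min(n_draw, raw[i].sum())
                sub = rng.multivariate_hypergeometric(raw[i], n_draw) if n_draw else raw[i] * 0
                rows.append(sub)
                labels.append(tumor_flag)
        boot_counts = np.array(rows)
        nonempty = boot_counts.sum(axis=1) > 0
        draws[b] = _discriminant_clr(
            _close_fractions(boot_counts[nonempty]),
            np.array(labels)[nonempty], basis,
        )
    return CompositionResult(
        coefficients=pd.Series(coef, index=keep, name="separating_coefficient"),
        bootstrap_draws=pd.DataFrame(draws, columns=keep),
    )
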