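"""Core data types, 10x-style IO, QC filters and depth normalization.

The central container is :class:`CellMatrix`, a genes × cells sparse count
matrix with per-cell metadata (sample, condition, cell type, 2-D embedding,
doublet score). It converts to/from :class:`anndata.AnnData` for
interoperability but the pipeline's statistics work on it directly.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "IntegrityError",
    "CellMatrix",
    "NormalizedMatrix",
    "GeneSet",
    "read_10x_mtx",
    "write_10x_mtx",
    "attach_metadata",
    "filter_cells",
    "normalize",
    "read_gene_sets",
    "write_gene_sets",
]

CONDITIONS = ("tumor", "normal")

META_COLUMNS = ("sample", "condition", "cell_type", "doublet_score")


class FormatError(ValueError):
    """A required input file is missing or unreadable."""


class IntegrityError(ValueError):
    """Input parsed but violates a structural invariant."""


@dataclass
class GeneSet:
    """A named collection of gene symbols (a signature module)."""

    name: str
    genes: list[str]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise IntegrityError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CellMatrix:
    """Sparse genes × cells counts plus per-cell metadata.

    ``obs`` is indexed by cell barcode and may carry the columns
    ``sample``, ``condition``, ``cell_type`` and ``doublet_score``;
    ``embedding`` is an optional (n_cells, 2) array.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    obs: pd.DataFrame = None
    embedding: np.ndarray | None = None

    def __post_init__(self):
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        if self.counts.nnz and self.counts.min() < 0:
            raise IntegrityError("counts matrix has negative entries")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise IntegrityError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise IntegrityError("duplicate gene symbols")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise IntegrityError("duplicate cell barcodes")
        if len(self.obs) != self.n_cells:
            raise IntegrityError("metadata length does not match cell count")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            if self.embedding.shape != (self.n_cells, 2):
                raise IntegrityError("embedding must be (n_cells, 2)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def total_umi(self) -> np.ndarray:
        """Per-cell total UMI (column sums of counts)."""
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(int)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def require_conditions(self) -> None:
        """Raise unless exactly two condition labels (tumor/normal) exist."""
        if "condition" not in self.obs:
            raise IntegrityError("no condition metadata attached")
        labels = set(self.obs["condition"].dropna().unique())
        if labels != set(CONDITIONS):
            raise IntegrityError(
                f"two-group stage needs conditions {set(CONDITIONS)}, got {labels}"
            )

    def subset(self, cell_mask) -> "CellMatrix":
        """New CellMatrix restricted to the given boolean mask / indices."""
        idx = np.arange(self.n_cells)[cell_mask]
        return CellMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            obs=self.obs.iloc[idx].copy(),
            embedding=None if self.embedding is None else self.embedding[idx],
        )

    # -- AnnData interop -------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )
        if self.embedding is not None:
            adata.obsm["X_embedding"] = self.embedding.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "CellMatrix":
        emb = adata.obsm.get("X_embedding")
        return cls(
            counts=sp.csc_matrix(adata.X.T),
            gene_ids=adata.var_names.to_numpy(object),
            cell_ids=adata.obs_names.to_numpy(object),
            obs=adata.obs.copy(),
            embedding=None if emb is None else np.asarray(emb),
        )


@dataclass
class NormalizedMatrix:
    """Depth-normalized, log-transformed genes × cells expression.

    Each cell is scaled to a common depth (``scale`` counts) and entries are
    mapped through ``log(1 + x / pseudocount)`` in the configured base, so an
    all-zero cell stays all-zero. Carries the metadata of the source
    :class:`CellMatrix` so downstream stages need only one object.
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    obs: pd.DataFrame
    embedding: np.ndarray | None
    provenance: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def dense(self, gene_idx=None) -> np.ndarray:
        m = self.values if gene_idx is None else self.values[gene_idx]
        return np.asarray(m.todense())


# ---------------------------------------------------------------------------
# 10x-style triplet IO
# ---------------------------------------------------------------------------

def _find(dir_path: Path, stems: list[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dir_path / name
            if p.exists():
                return p
    raise FormatError(f"missing file {stems[0]}(.gz) in {dir_path}")


def _read_tsv(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        if not first:
            return pd.DataFrame()
    return pd.read_csv(path, sep="\t", header=None, dtype=str)


def read_10x_mtx(dir_path, permissive: bool = False) -> CellMatrix:
    """Read a 10x-style triplet (matrix.mtx + features/genes.tsv + barcodes.tsv).

    ``permissive`` keeps the first occurrence of a duplicated gene symbol
    (logged) instead of raising.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, ["matrix.mtx"])
    gene_path = _find(dir_path, ["features.tsv", "genes.tsv"])
    bc_path = _find(dir_path, ["barcodes.tsv"])

    try:
        counts = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - wrap parser failures uniformly
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    counts = sp.csc_matrix(counts)
    if counts.nnz and counts.data.min() < 0:
        raise IntegrityError(f"{mtx_path} contains negative entries")

    genes_df = _read_tsv(gene_path)
    bc_df = _read_tsv(bc_path)
    if genes_df.empty or bc_df.empty:
        raise IntegrityError(
            f"empty annotation file ({gene_path.name if genes_df.empty else bc_path.name})"
            " for a non-empty matrix" if counts.shape[0] or counts.shape[1] else "empty input"
        )
    # features.tsv carries (id, symbol, type); bare genes.tsv may be 1 column
    symbols = genes_df.iloc[:, 1] if genes_df.shape[1] >= 2 else genes_df.iloc[:, 0]
    symbols = symbols.to_numpy(object)
    barcodes = bc_df.iloc[:, 0].to_numpy(object)

    if counts.shape != (len(symbols), len(barcodes)):
        raise IntegrityError(
            f"matrix is {counts.shape} but annotations give "
            f"{len(symbols)} genes x {len(barcodes)} barcodes"
        )

    dup = pd.Index(symbols).duplicated()
    if dup.any():
        if not permissive:
            raise IntegrityError(
                f"{dup.sum()} duplicated gene symbols (first: "
                f"{symbols[dup][0]!r}); pass permissive=True to keep first occurrences"
            )
        log.warning("dropping %d duplicated gene symbols (keeping first)", dup.sum())
        keep = ~dup
        counts, symbols = counts[keep], symbols[keep]

    return CellMatrix(counts=counts, gene_ids=symbols, cell_ids=barcodes)


def write_10x_mtx(cm: CellMatrix, dir_path, metadata: bool = True) -> Path:
    """Write the triplet (plus a per-cell metadata TSV) readable by read_10x_mtx."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(_as_integer(cm.counts)))
    pd.DataFrame({0: cm.gene_ids, 1: cm.gene_ids}).to_csv(
        dir_path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(cm.cell_ids).to_csv(dir_path / "barcodes.tsv", sep="\t", header=False, index=False)
    if metadata and (len(cm.obs.columns) or cm.embedding is not None):
        meta = cm.obs.copy()
        if cm.embedding is not None:
            meta["x"], meta["y"] = cm.embedding[:, 0], cm.embedding[:, 1]
        meta.index.name = "barcode"
        meta.to_csv(dir_path / "metadata.tsv", sep="\t")
    return dir_path


def _as_integer(m: sp.spmatrix) -> sp.spmatrix:
    """Coerce to integer dtype when all entries are integral (MTX round-trip)."""
    if np.allclose(m.data, np.round(m.data)):
        out = m.copy()
        out.data = np.round(out.data).astype(np.int64)
        return out
    return m


def attach_metadata(cm: CellMatrix, table, permissive: bool = False) -> CellMatrix:
    """Join a per-cell metadata table (TSV path or DataFrame) by barcode.

    Recognized columns: ``sample``, ``condition``, ``cell_type``, ``x``,
    ``y``, ``doublet_score``. Cells absent from the table raise unless
    ``permissive`` is set, in which case they are dropped and counted.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", index_col=0)
    if table.index.duplicated().any():
        raise IntegrityError("metadata table has duplicate barcodes")
    known = set(META_COLUMNS) | {"x", "y"}
    extra = [c for c in table.columns if c not in known]
    if extra:
        log.info("ignoring metadata columns %s", extra)

    present = np.isin(cm.cell_ids.astype(str), table.index.astype(str))
    if not present.all():
        n_missing = int((~present).sum())
        if not permissive:
            raise IntegrityError(
                f"{n_missing} cells missing from metadata table; "
                "pass permissive=True to drop them"
            )
        log.warning("dropping %d cells absent from metadata table", n_missing)
        cm = cm.subset(present)

    aligned = table.reindex(pd.Index(cm.cell_ids.astype(str)))
    obs = cm.obs.copy()
    for col in META_COLUMNS:
        if col in aligned:
            obs[col] = aligned[col].to_numpy()
    if "doublet_score" in obs:
        obs["doublet_score"] = obs["doublet_score"].astype(float)
        bad = obs["doublet_score"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise IntegrityError("doublet_score outside [0, 1]")
    emb = cm.embedding
    if {"x", "y"} <= set(aligned.columns):
        emb = aligned[["x", "y"]].to_numpy(float)
    return CellMatrix(cm.counts, cm.gene_ids, cm.cell_ids, obs=obs, embedding=emb)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def filter_cells(cm: CellMatrix, min_umi: int = 700, max_doublet: float | None = 0.4) -> CellMatrix:
    """QC filter: keep cells with total UMI ≥ ``min_umi`` and (when doublet
    scores are present and ``max_doublet`` is not None) doublet score ≤
    ``max_doublet``. Idempotent; removal counts are logged per sample."""
    keep = cm.total_umi >= min_umi
    low_umi = ~keep
    doublet = np.zeros(cm.n_cells, dtype=bool)
    if max_doublet is not None and "doublet_score" in cm.obs:
        score = cm.obs["doublet_score"].to_numpy(float)
        doublet = np.nan_to_num(score, nan=0.0) > max_doublet
        keep &= ~doublet
    if "sample" in cm.obs:
        per_sample = pd.DataFrame(
            {"low_umi": low_umi, "doublet": doublet, "sample": cm.obs["sample"].to_numpy()}
        ).groupby("sample").sum()
        for s, row in per_sample.iterrows():
            if row.sum():
                log.info("QC %s: removed %d low-UMI, %d doublet cells", s,
                         row["low_umi"], row["doublet"])
    else:
        log.info("QC: removed %d low-UMI, %d doublet cells", low_umi.sum(), doublet.sum())
    out = cm.subset(keep)
    if out.n_cells == 0:
        log.warning("QC removed every cell")
    return out


def normalize(cm: CellMatrix, scale: float = 1e4, pseudocount: float = 1.0,
              log_base: float = np.e) -> NormalizedMatrix:
    """Depth-normalize each cell to ``scale`` total counts, then apply
    ``log(1 + x / pseudocount)`` in ``log_base``. All-zero cells stay zero;
    proportional cells map to identical columns."""
    totals = cm.total_umi.astype(float)
    inv = np.divide(scale, totals, out=np.zeros_like(totals), where=totals > 0)
    values = cm.counts.astype(float).multiply(sp.csr_matrix(inv[None, :])).tocsc()
    values.data = np.log1p(values.data / pseudocount) / np.log(log_base)
    return NormalizedMatrix(
        values=values,
        gene_ids=cm.gene_ids,
        cell_ids=cm.cell_ids,
        obs=cm.obs.copy(),
        embedding=None if cm.embedding is None else cm.embedding.copy(),
        provenance={"scale": scale, "pseudocount": pseudocount, "log_base": log_base},
    )


# ---------------------------------------------------------------------------
# Gene-set files (two-column TSV or GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> dict[str, GeneSet]:
    """Read gene sets from a two-column TSV (set name, symbol) or a GMT file."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sets[parts[0]] = [g for g in parts[2:] if g]
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        for name, grp in df.groupby(0, sort=False):
            sets[name] = grp[1].tolist()
    out = {}
    for name, genes in sets.items():
        if not genes:
            raise IntegrityError(f"gene set {name!r} is empty")
        out[name] = GeneSet(name, list(dict.fromkeys(genes)))
    return out


def write_gene_sets(gene_sets, path) -> Path:
    """Write gene sets as a two-column TSV consumable by read_gene_sets."""
    path = Path(path)
    rows = [(gs.name, g) for gs in gene_sets for g in gs.genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return path
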