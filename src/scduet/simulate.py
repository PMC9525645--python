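"""Synthetic multi-sample tumor/normal single-cell cohorts and bulk survival
cohorts with planted, parameterized effects.

The generator emulates the statistical structure the comparison pipeline
assumes: negative-binomial counts per gene (variance μ + μ²/θ) with
multiplicative cell-type, condition and depth effects; per-sample cell-type
compositions drawn from a Dirichlet around condition-specific target
proportions; Gaussian-blob 2-D embeddings per cell type; Beta-distributed
doublet scores with a planted high-score fraction; and bulk cohorts whose
exponential hazard is log-linear in a signature score. One global seed fully
determines the output via named `numpy.random.SeedSequence` child streams.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CellMatrix, GeneSet, IntegrityError
from .survival import SurvivalCohort

__all__ = [
    "ConfigError",
    "DEEffect",
    "LRPlant",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_bulk_survival",
]


class ConfigError(ValueError):
    """Simulation configuration violates a constraint."""


@dataclass
class DEEffect:
    """A planted condition-specific expression change in one cell type."""

    cell_type: str
    condition: str
    genes: list[str]
    log2fc: float


@dataclass
class LRPlant:
    """A planted ligand-receptor co-elevation: the ligand is elevated in the
    sender type and the receptor in the receiver type (fold = effect)."""

    ligand: str
    sender: str
    receptor: str
    receiver: str
    effect: float


@dataclass
class SimulationConfig:
    """Study conditions for a matched tumor/adjacent-normal cohort.

    Defaults emulate a small multi-patient 10x-style study: 10 samples per
    condition, ~300 cells each, 5 cell types with markers, moderate
    inter-sample compositional noise (Dirichlet concentration 50).
    """

    n_samples_per_condition: int = 10
    cells_mean: float = 300.0
    cells_shape: float = 20.0  # NB shape for per-sample cell counts
    cell_types: dict[str, float] = field(
        default_factory=lambda: {
            "tumor": 0.30, "endothelial": 0.15, "fibroblast": 0.15,
            "macrophage": 0.20, "tcell": 0.20,
        }
    )
    composition_effects: dict[str, float] = field(default_factory=dict)
    n_genes: int = 500
    mean_log_mu: float = 0.0     # lognormal law of baseline per-gene NB means
    mean_log_sigma: float = 1.0
    dispersion: float = 10.0     # NB shape θ (variance μ + μ²/θ)
    n_markers_per_type: int = 10
    marker_fold: float = 8.0
    de_effects: list[DEEffect] = field(default_factory=list)
    lr_plants: list[LRPlant] = field(default_factory=list)
    embedding_radius: float = 5.0
    embedding_sd: float = 0.6
    depth_range: tuple[float, float] = (0.5, 2.0)
    doublet_rate: float = 0.05
    dirichlet_conc: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        props = np.array(list(self.cell_types.values()), dtype=float)
        if (props <= 0).any() or not np.isclose(props.sum(), 1.0, atol=1e-6):
            raise ConfigError("cell-type baseline proportions must be positive and sum to 1")
        if self.dispersion <= 0 or self.cells_shape <= 0:
            raise ConfigError("NB dispersions must be > 0")
        for t, eff in self.composition_effects.items():
            if t not in self.cell_types:
                raise ConfigError(f"composition effect on unknown type {t!r}")
            if eff <= 0:
                raise ConfigError("composition effects must be positive multiplicative shifts")
        for plant in self.lr_plants:
            if plant.effect <= 0:
                raise ConfigError("LR plant effects must be positive")
        if not (0 <= self.doublet_rate < 1):
            raise ConfigError("doublet_rate must be in [0, 1)")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ConfigError("depth_range must be positive and ordered")


@dataclass
class GroundTruth:
    """Planted truth emitted next to the simulated cohort."""

    cell_type: pd.Series
    marker_genes: dict[str, list[str]]
    de_genes: dict[tuple[str, str], list[str]]
    composition_effects: dict[str, float]
    lr_plants: list[LRPlant]

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "cell_type": self.cell_type.to_dict(),
            "marker_genes": self.marker_genes,
            "de_genes": {f"{t}|{c}": g for (t, c), g in self.de_genes.items()},
            "composition_effects": self.composition_effects,
            "lr_plants": [asdict(p) for p in self.lr_plants],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


_STREAMS = ("composition", "counts", "embedding", "doublets", "depth", "sizes")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def simulate_cohort(config: SimulationConfig) -> tuple[CellMatrix, GroundTruth]:
    """Draw a two-condition cohort under the configured study conditions."""
    config.validate()
    rngs = _streams(config.seed)
    types = list(config.cell_types)
    genes = np.array([f"G{i:04d}" for i in range(config.n_genes)], dtype=object)

    # Baseline per-gene means and per-type marker assignments.
    base_mu = rngs["counts"].lognormal(config.mean_log_mu, config.mean_log_sigma,
                                       size=config.n_genes)
    marker_genes: dict[str, list[str]] = {}
    # mean multiplier per (type, condition): genes x types x 2
    cond_names = ("tumor", "normal")
    mult = np.ones((config.n_genes, len(types), 2))
    gi = {g: i for i, g in enumerate(genes)}
    cursor = 0
    for k, t in enumerate(types):
        idx = np.arange(cursor, min(cursor + config.n_markers_per_type, config.n_genes))
        cursor += config.n_markers_per_type
        marker_genes[t] = list(genes[idx])
        mult[idx, k, :] *= config.marker_fold
    de_genes: dict[tuple[str, str], list[str]] = {}
    for eff in config.de_effects:
        k, c = types.index(eff.cell_type), cond_names.index(eff.condition)
        rows = [gi[g] for g in eff.genes]
        mult[rows, k, c] *= 2.0 ** eff.log2fc
        de_genes.setdefault((eff.cell_type, eff.condition), []).extend(eff.genes)
    for plant in config.lr_plants:
        mult[gi[plant.ligand], types.index(plant.sender), :] *= plant.effect
        mult[gi[plant.receptor], types.index(plant.receiver), :] *= plant.effect

    # Condition-specific target compositions.
    base_props = np.array(list(config.cell_types.values()))
    tumor_props = base_props.copy()
    for t, eff in config.composition_effects.items():
        tumor_props[types.index(t)] *= eff
    tumor_props = tumor_props / tumor_props.sum()
    targets = {"tumor": tumor_props, "normal": base_props}

    centers = config.embedding_radius * np.stack(
        [np.cos(2 * np.pi * np.arange(len(types)) / len(types)),
         np.sin(2 * np.pi * np.arange(len(types)) / len(types))], axis=1
    )

    blocks, cell_ids, obs_rows, emb_rows = [], [], [], []
    lo, hi = np.log(config.depth_range[0]), np.log(config.depth_range[1])
    for cond in cond_names:
        for j in range(config.n_samples_per_condition):
            sample = f"{cond[0].upper()}{j + 1:02d}"
            n_cells = 1 + rngs["sizes"].negative_binomial(
                config.cells_shape,
                config.cells_shape / (config.cells_shape + config.cells_mean - 1),
            )
            props = rngs["composition"].dirichlet(config.dirichlet_conc * targets[cond])
            type_idx = rngs["composition"].choice(len(types), size=n_cells, p=props)
            depth = np.exp(rngs["depth"].uniform(lo, hi, size=n_cells))
            for k in range(len(types)):
                cells_k = np.where(type_idx == k)[0]
                if cells_k.size == 0:
                    continue
                mu = (base_mu * mult[:, k, cond_names.index(cond)])[:, None] * depth[cells_k][None, :]
                lam = rngs["counts"].gamma(config.dispersion, mu / config.dispersion)
                blocks.append((sample, cond, types[k], cells_k,
                               rngs["counts"].poisson(lam)))
            emb = centers[type_idx] + rngs["embedding"].normal(
                0, config.embedding_sd, size=(n_cells, 2))
            scores = rngs["doublets"].beta(1.5, 15.0, size=n_cells)
            n_doub = rngs["doublets"].binomial(n_cells, config.doublet_rate)
            if n_doub:
                hit = rngs["doublets"].choice(n_cells, size=n_doub, replace=False)
                scores[hit] = rngs["doublets"].beta(8.0, 2.0, size=n_doub)
            for i in range(n_cells):
                cell_ids.append(f"{sample}-{i:05d}")
                obs_rows.append((sample, cond, types[type_idx[i]], scores[i]))
            emb_rows.append(emb)

    n_total = len(cell_ids)
    counts = np.zeros((config.n_genes, n_total), dtype=np.int64)
    offsets, off = {}, 0
    for cond in cond_names:
        for j in range(config.n_samples_per_condition):
            sample = f"{cond[0].upper()}{j + 1:02d}"
            offsets[sample] = off
            off += sum(1 for r in obs_rows if r[0] == sample)
    for sample, cond, t, cells_k, block in blocks:
        counts[:, offsets[sample] + cells_k] = block

    obs = pd.DataFrame(
        obs_rows, columns=["sample", "condition", "cell_type", "doublet_score"],
        index=pd.Index(cell_ids, name="cell"),
    )
    cm = CellMatrix(
        counts=sp.csc_matrix(counts),
        gene_ids=genes,
        cell_ids=np.array(cell_ids, dtype=object),
        obs=obs,
        embedding=np.vstack(emb_rows),
    )
    truth = GroundTruth(
        cell_type=obs["cell_type"].copy(),
        marker_genes=marker_genes,
        de_genes=de_genes,
        composition_effects=dict(config.composition_effects),
        lr_plants=list(config.lr_plants),
    )
    return cm, truth


def simulate_bulk_survival(n_samples: int, genes: list[str], signature: GeneSet,
                           hazard_log_hr: float, censor_rate: float, seed: int,
                           base_scale: float = 60.0) -> SurvivalCohort:
    """Bulk cohort with exponential survival log-linear in a signature score.

    Expression is standard Gaussian on the log scale; the event time is
    exponential with rate ∝ exp(hazard_log_hr × standardized signature mean);
    censoring is an independent exponential tuned so that roughly
    ``censor_rate`` of samples are censored under the null.
    """
    if not set(signature.genes) <= set(genes):
        raise IntegrityError("signature must be a subset of the cohort gene list")
    if len(signature) == 0:
        raise IntegrityError("empty signature")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    expr = pd.DataFrame(
        rng.normal(size=(n_samples, len(genes))),
        index=[f"S{i + 1:04d}" for i in range(n_samples)],
        columns=list(genes),
    )
    score = expr[signature.genes].mean(axis=1)
    score = (score - score.mean()) / max(score.std(ddof=0), 1e-12)
    event_time = rng.exponential(base_scale * np.exp(-hazard_log_hr * score.to_numpy()))
    if censor_rate <= 0:
        time, event = event_time, np.ones(n_samples, dtype=bool)
    else:
        censor_scale = base_scale * (1 - censor_rate) / censor_rate
        censor_time = rng.exponential(censor_scale, size=n_samples)
        event = event_time <= censor_time
        time = np.minimum(event_time, censor_time)
    return SurvivalCohort(
        expression=expr,
        time=pd.Series(time, index=expr.index),
        event=pd.Series(event, index=expr.index),
    )
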