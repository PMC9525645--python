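"""Config-driven orchestration of the comparison pipeline.

A single :class:`PipelineConfig` (YAML/JSON-loadable, unknown keys rejected)
carries input paths, stage toggles and every stage parameter. Two frozen
profiles exist: ``paper`` (the study's stated parameter values) and ``test``
(desk-scale sizes for quick runs). :func:`run` executes the enabled stages
in dependency order — QC → normalize → scoring / abundance / distance /
markers → signature → interactions, with survival independent — writing
each stage's tables plus a manifest (parameters, input hashes, seed,
runtime) into the output directory.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, distance, interactions, markers, signatures, survival
from .data import (CellMatrix, GeneSet, attach_metadata, filter_cells, normalize,
                   read_10x_mtx, read_gene_sets)
from .interactions import read_lr_pairs
from .simulate import SimulationConfig, simulate_bulk_survival, simulate_cohort
from .survival import read_survival_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PAPER_PROFILE", "TEST_PROFILE", "run"]

# Stage parameters as printed in the study the pipeline reimplements.
PAPER_PROFILE = dict(
    min_umi=700, max_doublet=0.4, lr_min_frac=0.10, marker_z_min=3.0,
    n_perm=1000, n_boot_survival=100, quantile=0.95, strat_q=0.25,
    gridsize=400, pseudobulk_min_cells=10, min_cells_per_sample=40,
    n_rounds=100, coda_n_boot=1000, coda_cells_per_boot=1000,
)
# Desk-scale profile for fast synthetic runs.
TEST_PROFILE = dict(
    PAPER_PROFILE, gridsize=100, n_perm=200, n_rounds=10,
    coda_n_boot=200, coda_cells_per_boot=500,
)


@dataclass
class PipelineConfig:
    """All inputs, toggles and parameters of one pipeline run."""

    # inputs (None -> the synthetic generator provides the data)
    matrix_dir: str | None = None
    metadata: str | None = None
    gene_sets: str | None = None
    lr_table: str | None = None
    bulk_cohort: str | None = None
    signature: list[str] | None = None

    # stage toggles
    do_qc: bool = True
    do_score: bool = True
    do_abundance: bool = True
    do_distance: bool = True
    do_markers: bool = True
    do_signature: bool = False
    do_interactions: bool = True
    do_survival: bool = False

    # stage parameters (paper defaults)
    min_umi: int = 700
    max_doublet: float = 0.4
    scale: float = 1e4
    pseudocount: float = 1.0
    lr_min_frac: float = 0.10
    marker_z_min: float = 3.0
    n_perm: int = 1000
    n_boot_survival: int = 100
    quantile: float = 0.95
    strat_q: float = 0.25
    gridsize: int = 400
    pseudobulk_min_cells: int = 10
    min_cells_per_sample: int = 40
    n_rounds: int = 100
    coda_n_boot: int = 1000
    coda_cells_per_boot: int = 1000
    signature_target: str = "C4"
    signature_top_n: int = 100
    seed: int = 0

    # synthetic-cohort knobs (used when matrix_dir is None)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path, profile: str | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, profile=profile)

    @classmethod
    def from_dict(cls, raw: dict, profile: str | None = None) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(raw)
        if profile:
            prof = {"paper": PAPER_PROFILE, "test": TEST_PROFILE}[profile]
            for k, v in prof.items():
                merged.setdefault(k, v)
        return cls(**merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: PipelineConfig, outdir) -> Path:
    """Execute the enabled stages; returns the output directory.

    Raises a dependency error naming the missing upstream requirement when a
    stage's inputs are not available (e.g. interactions without cell types).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "inputs": {}}
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    def record(stage, t0, **extra):
        manifest["stages"].append(
            {"stage": stage, "runtime_s": round(time.perf_counter() - t0, 3),
             "status": "success", **extra}
        )

    # ---- load or simulate -------------------------------------------------
    t0 = time.perf_counter()
    truth = None
    if config.matrix_dir:
        cm = read_10x_mtx(config.matrix_dir)
        manifest["inputs"]["matrix_dir"] = str(config.matrix_dir)
        if config.metadata:
            cm = attach_metadata(cm, config.metadata)
            manifest["inputs"]["metadata"] = _hash_file(Path(config.metadata))
    else:
        sim_cfg = SimulationConfig(**{**config.sim, "seed": config.seed})
        cm, truth = simulate_cohort(sim_cfg)
        truth.to_json(outdir / "ground_truth.json")
    record("load", t0, n_cells=cm.n_cells, n_genes=cm.n_genes)

    if config.do_qc:
        t0 = time.perf_counter()
        before = cm.n_cells
        cm = filter_cells(cm, min_umi=config.min_umi, max_doublet=config.max_doublet)
        record("qc", t0, cells_in=before, cells_out=cm.n_cells)

    nm = normalize(cm, scale=config.scale, pseudocount=config.pseudocount)

    gene_sets = None
    if config.gene_sets:
        gene_sets = read_gene_sets(config.gene_sets)
    elif truth is not None:
        gene_sets = {t: GeneSet(t, g) for t, g in truth.marker_genes.items()}

    if config.do_score:
        if gene_sets is None:
            raise ValueError("scoring stage needs gene_sets (missing upstream input)")
        t0 = time.perf_counter()
        table = signatures.compare_table(nm, list(gene_sets.values()))
        table.to_csv(outdir / "signature_comparisons.tsv", sep="\t", index=False)
        record("score", t0, n_sets=len(gene_sets))

    if config.do_abundance:
        if "cell_type" not in cm.obs:
            raise ValueError("abundance stage needs cell_type metadata")
        t0 = time.perf_counter()
        props = abundance.proportion_tests(cm)
        props.to_csv(outdir / "proportion_tests.tsv", sep="\t", index=False)
        counts = cm.obs.groupby(["sample", "cell_type"]).size().unstack(fill_value=0)
        cond = cm.obs.groupby("sample")["condition"].agg(lambda s: s.mode().iat[0])
        coda = abundance.coda_coefficients(
            counts, cond, n_boot=config.coda_n_boot,
            cells_per_boot=config.coda_cells_per_boot, seed=config.seed,
        )
        coda.quantiles().assign(coefficient=coda.coefficients).to_csv(
            outdir / "coda_coefficients.tsv", sep="\t")
        if cm.embedding is not None:
            dg = abundance.estimate_density(cm, gridsize=config.gridsize)
            dg = abundance.quantile_normalize_grids(dg)
            diff = abundance.density_diff(dg)
            ii, jj = np.nonzero(diff.mask)
            pd.DataFrame({"bin_x": ii, "bin_y": jj, "z": diff.z[ii, jj]}).to_csv(
                outdir / "density_diff.tsv", sep="\t", index=False)
        record("abundance", t0)

    if config.do_distance:
        if "cell_type" not in cm.obs or "sample" not in cm.obs:
            raise ValueError("distance stage needs sample and cell_type metadata")
        t0 = time.perf_counter()
        pb = distance.make_pseudobulk(cm, min_cells=config.pseudobulk_min_cells)
        res = distance.celltype_distance(
            cm, min_cells=config.pseudobulk_min_cells,
            n_rounds=config.n_rounds, seed=config.seed)
        distance.distance_permutation_test(res, n_perm=config.n_perm, seed=config.seed)
        pd.DataFrame({"normalized_distance": res.normalized_distance,
                      "permutation_p": res.permutation_p}).to_csv(
            outdir / "expression_distance.tsv", sep="\t")
        smap = distance.overall_sample_distance(pb)
        smap.distance_matrix.to_csv(outdir / "sample_distance_matrix.tsv", sep="\t")
        smap.mds_coords.to_csv(outdir / "sample_mds.tsv", sep="\t")
        record("distance", t0)

    marker_table = None
    if config.do_markers or config.do_interactions:
        if "cell_type" not in cm.obs:
            raise ValueError("marker stage needs cell_type metadata")
        t0 = time.perf_counter()
        marker_table = markers.marker_genes(nm, cm.obs["cell_type"],
                                            z_min=config.marker_z_min)
        marker_table.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        record("markers", t0, n_markers=int(marker_table["is_marker"].sum()))

    if config.do_signature:
        if "subclone" not in cm.obs:
            raise ValueError("signature stage needs subclone labels (missing upstream)")
        t0 = time.perf_counter()
        sel = markers.select_metastatic_signature(
            nm, cm.obs["subclone"], target=config.signature_target,
            top_n=config.signature_top_n)
        pd.Series(sel.final.genes).to_csv(outdir / "metastatic_signature.tsv",
                                          sep="\t", index=False, header=False)
        record("signature", t0, n_genes=len(sel.final))

    if config.do_interactions:
        if "cell_type" not in cm.obs:
            raise ValueError("interactions stage needs cell_type metadata")
        t0 = time.perf_counter()
        if config.lr_table:
            pairs = read_lr_pairs(config.lr_table)
            manifest["inputs"]["lr_table"] = _hash_file(Path(config.lr_table))
        elif truth is not None:
            # planted pairs plus seeded decoys so the stage exercises the null
            rng = np.random.default_rng(config.seed)
            rows = [{"ligand": p.ligand, "receptor": p.receptor,
                     "pair_id": f"{p.ligand}_{p.receptor}"} for p in truth.lr_plants]
            decoys = rng.choice(cm.gene_ids, size=(20, 2), replace=False)
            rows += [{"ligand": l, "receptor": r, "pair_id": f"{l}_{r}"}
                     for l, r in decoys]
            pairs = interactions.LRPairTable(pd.DataFrame(rows).drop_duplicates("pair_id"))
        else:
            raise ValueError("interactions stage needs an LR pair table")
        cands = interactions.screen_pairs(nm, pairs, min_frac=config.lr_min_frac)
        if len(cands):
            cands = interactions.permutation_test(nm, cands, n_perm=config.n_perm,
                                                  seed=config.seed)
            cands = interactions.specificity_filter(marker_table, cands,
                                                    z_min=config.marker_z_min)
        cands.to_csv(outdir / "lr_results.tsv", sep="\t", index=False)
        record("interactions", t0, n_triples=len(cands))

    if config.do_survival:
        t0 = time.perf_counter()
        if config.bulk_cohort:
            cohort = read_survival_cohort(config.bulk_cohort)
            manifest["inputs"]["bulk_cohort"] = _hash_file(Path(config.bulk_cohort))
            if not config.signature:
                raise ValueError("survival stage needs a signature gene list")
            sig = GeneSet("signature", list(config.signature))
        else:
            genes = [f"G{i:04d}" for i in range(200)]
            sig = GeneSet("signature", genes[:10])
            cohort = simulate_bulk_survival(300, genes, sig, hazard_log_hr=0.7,
                                            censor_rate=0.3, seed=config.seed)
        res = survival.reproducibility_power(
            cohort, sig, n_boot=config.n_boot_survival,
            quantile=config.quantile, seed=config.seed, q=config.strat_q)
        json.dump({"p": res.p, "power_p": res.power_p,
                   "bootstrap_p": res.bootstrap_p.tolist()},
                  open(outdir / "survival.json", "w"), indent=1)
        record("survival", t0, power_p=res.power_p)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
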