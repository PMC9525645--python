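"""Signature-stratified survival analysis on bulk cohorts.

Samples are scored by the mean log-scale expression of a gene signature,
stratified into top/bottom quartiles, and compared with a two-sided log-rank
test. The stability of a signature is summarized by the "reproducibility
power" p-value: the 0.95 quantile of log-rank p-values over bootstrap
resamples of the signature's genes — a signature whose association survives
most gene resamples keeps a small power p.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .data import GeneSet, IntegrityError

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalCohort",
    "StratifiedTest",
    "read_survival_cohort",
    "signature_score",
    "stratify_quartiles",
    "logrank",
    "reproducibility_power",
    "plot_km",
]


@dataclass
class SurvivalCohort:
    """Bulk expression (samples × genes, log scale) with follow-up."""

    expression: pd.DataFrame
    time: pd.Series
    event: pd.Series
    stage: pd.Series | None = None

    def __post_init__(self):
        if self.expression.columns.duplicated().any():
            raise IntegrityError("duplicate gene columns in cohort expression")
        if (np.asarray(self.time, dtype=float) < 0).any():
            raise IntegrityError("negative follow-up times")
        for s in (self.time, self.event):
            if not s.index.equals(self.expression.index):
                raise IntegrityError("clinical series not aligned with expression samples")

    @property
    def n_samples(self) -> int:
        return len(self.expression)


def read_survival_cohort(path, clinical_path=None, time_col: str = "time",
                         event_col: str = "event", stage_col: str = "stage",
                         log1p: bool = False) -> SurvivalCohort:
    """Load a cohort from a wide TSV (sample, time, event[, stage], genes...)
    or from an expression TSV joined with a clinical TSV on sample id.

    ``log1p`` applies log1p to the expression for raw-count cohorts.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if clinical_path is not None:
        clin = pd.read_csv(clinical_path, sep="\t", index_col=0)
        common = expr.index.intersection(clin.index)
        expr, clin = expr.loc[common], clin.loc[common]
    else:
        clin_cols = [c for c in (time_col, event_col, stage_col) if c in expr.columns]
        clin = expr[clin_cols]
        expr = expr.drop(columns=clin_cols)
    if log1p:
        expr = np.log1p(expr)
    stage = clin[stage_col] if stage_col in clin else None
    return SurvivalCohort(
        expression=expr,
        time=clin[time_col].astype(float),
        event=clin[event_col].astype(float).astype(bool),
        stage=stage,
    )


def signature_score(cohort: SurvivalCohort, signature: GeneSet) -> pd.Series:
    """Per-sample mean expression over the signature genes present."""
    present = [g for g in signature.genes if g in cohort.expression.columns]
    if len(present) < 1:
        raise IntegrityError(f"no signature genes present in cohort ({signature.name})")
    missing = set(signature.genes) - set(present)
    if missing:
        log.info("signature %s: %d genes absent from cohort", signature.name, len(missing))
    return cohort.expression[present].mean(axis=1)


def stratify_quartiles(scores: pd.Series, q: float = 0.25) -> pd.Series:
    """Assign the top ⌊qn⌋ scores to 'high', the bottom ⌊qn⌋ to 'low', and
    exclude the rest. Ties are broken by stable sample order (logged)."""
    n = len(scores)
    if n < 8:
        raise ValueError(f"need at least 8 samples to stratify, got {n}")
    vals = scores.to_numpy(float)
    if np.ptp(vals) == 0:
        raise ValueError("all scores identical: no stratification possible")
    k = int(np.floor(q * n))
    order = np.argsort(vals, kind="stable")
    groups = pd.Series("excluded", index=scores.index, name="group")
    groups.iloc[order[:k]] = "low"
    groups.iloc[order[-k:]] = "high"
    for cut, side in ((vals[order[k - 1]], "low"), (vals[order[-k]], "high")):
        n_tied = int((vals == cut).sum())
        if n_tied > 1:
            log.info("%d samples tied at the %s cutoff %.4g; stable order used",
                     n_tied, side, cut)
    return groups


def logrank(groups: pd.Series, time: pd.Series, event: pd.Series) -> tuple[float, float]:
    """Two-sided log-rank test between the 'high' and 'low' groups.

    Returns the 1-df chi-square statistic and its tail p. With zero observed
    events the statistic is 0 by convention (warned).
    """
    hi, lo = groups == "high", groups == "low"
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("both 'high' and 'low' groups must be non-empty")
    ev = event[hi | lo]
    if ev.sum() == 0:
        warnings.warn("no events observed; log-rank statistic set to 0", stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(time[hi], time[lo], event_observed_A=event[hi].astype(int),
                       event_observed_B=event[lo].astype(int))
    return float(res.test_statistic), float(res.p_value)


@dataclass
class StratifiedTest:
    """Result of a signature-stratified survival analysis."""

    groups: pd.Series
    statistic: float
    p: float
    bootstrap_p: np.ndarray = field(default_factory=lambda: np.array([]))
    power_p: float = np.nan
    quantile: float = 0.95


def reproducibility_power(cohort: SurvivalCohort, signature: GeneSet,
                          n_boot: int = 100, quantile: float = 0.95,
                          seed: int | None = None, q: float = 0.25) -> StratifiedTest:
    """Bootstrap-stabilized stratified log-rank analysis.

    Each round resamples the signature genes with replacement (same size),
    recomputes the score, restratifies and retests; ``power_p`` is the
    ``quantile`` (default 0.95) of the bootstrap p-values, with the
    unresampled p reported alongside.
    """
    present = [g for g in signature.genes if g in cohort.expression.columns]
    if len(present) < 2:
        raise IntegrityError(
            f"signature {signature.name!r} shares {len(present)} gene(s) with the "
            "cohort; at least 2 required"
        )
    base = GeneSet(signature.name, present)
    groups = stratify_quartiles(signature_score(cohort, base), q=q)
    stat, p = logrank(groups, cohort.time, cohort.event)

    rng = np.random.default_rng(seed)
    expr = cohort.expression[present].to_numpy(float)
    ps = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(present), size=len(present))
        score = pd.Series(expr[:, pick].mean(axis=1), index=cohort.expression.index)
        try:
            g = stratify_quartiles(score, q=q)
            _, ps[b] = logrank(g, cohort.time, cohort.event)
        except ValueError:  # degenerate resample (constant scores)
            ps[b] = 1.0
    return StratifiedTest(
        groups=groups, statistic=stat, p=p, bootstrap_p=ps,
        power_p=float(np.quantile(ps, quantile)), quantile=quantile,
    )


def plot_km(cohort: SurvivalCohort, groups: pd.Series, path) -> Path:
    """Kaplan-Meier curves for the high/low strata (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, color in (("high", "firebrick"), ("low", "steelblue")):
        mask = groups == name
        KaplanMeierFitter(label=f"{name} (n={int(mask.sum())})").fit(
            cohort.time[mask], cohort.event[mask].astype(int)
        ).plot_survival_function(ax=ax, color=color)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
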