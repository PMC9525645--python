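import logging

import numpy as np
import pandas as pd
import pytest

from scduet import normalize
from scduet.simulate import SimulationConfig, simulate_cohort

logging.getLogger("scduet").setLevel(logging.ERROR)


def small_config(**kw) -> SimulationConfig:
    """A fast desk-scale cohort configuration; overridable per test."""
    base = dict(n_samples_per_condition=5, cells_mean=150, n_genes=200, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """One seeded cohort shared by read-only tests."""
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def cm(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def truth(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def nm(cm):
    return normalize(cm)


@pytest.fixture(scope="session")
def sample_conditions(cm) -> pd.Series:
    return cm.obs.groupby("sample")["condition"].agg(lambda s: s.mode().iat[0])


def toy_cell_matrix(counts, samples=None, conditions=None, cell_types=None,
                    embedding=None, doublet=None):
    """Build a CellMatrix from a dense genes x cells array with toy metadata."""
    from scduet.data import CellMatrix

    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell"))
    for name, vals in (("sample", samples), ("condition", conditions),
                       ("cell_type", cell_types), ("doublet_score", doublet)):
        if vals is not None:
            obs[name] = list(vals)
    return CellMatrix(
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        cell_ids=obs.index.to_numpy(object),
        obs=obs,
        embedding=embedding,
    )
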