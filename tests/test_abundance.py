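import numpy as np
import pandas as pd
import pytest
from scipy.linalg import helmert
from scipy.stats import ortho_group
from skbio.stats.composition import clr

from scduet import abundance
from scduet.abundance import (celltype_fractions, coda_coefficients, density_diff,
                              estimate_density, ilr_basis, proportion_tests,
                              quantile_normalize_grids)
from scduet.simulate import simulate_cohort

from conftest import small_config, toy_cell_matrix


def _embedded_cm(n_per_sample=40, samples=("t1", "t2", "n1", "n2"), seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_sample * len(samples)
    emb = rng.normal(size=(n, 2))
    return toy_cell_matrix(
        np.ones((3, n), dtype=int),
        samples=np.repeat(samples, n_per_sample),
        conditions=np.repeat(["tumor" if s.startswith("t") else "normal"
                              for s in samples], n_per_sample),
        embedding=emb,
    )


class TestDensity:
    def test_density_integrates_to_one(self):
        cm = _embedded_cm()
        dg = estimate_density(cm, gridsize=40)
        for g in dg.grids.values():
            assert g.min() >= 0
            assert g.sum() * dg.bin_area == pytest.approx(1.0, abs=1e-6)

    def test_identical_coordinates_identical_grids(self):
        cm = _embedded_cm(samples=("t1", "t2", "n1", "n2"), seed=1)
        # force t1 and t2 onto the same coordinates
        cm.embedding[40:80] = cm.embedding[:40]
        dg = estimate_density(cm, gridsize=30)
        assert np.allclose(dg.grids["t1"], dg.grids["t2"])

    def test_small_sample_excluded(self):
        cm = _embedded_cm()
        cm.obs.loc[cm.obs.index[:75], "sample"] = "t1"  # leaves t2 with 5 cells
        dg = estimate_density(cm, gridsize=20)
        assert "t2" not in dg.grids

    def test_single_peak_decreases_radially(self):
        rng = np.random.default_rng(3)
        emb = np.vstack([rng.normal(0, 0.3, size=(60, 2))])
        cm = toy_cell_matrix(np.ones((2, 60), dtype=int),
                             samples=["s1"] * 60, embedding=emb)
        dg = estimate_density(cm, gridsize=31)
        g = dg.grids["s1"]
        peak = np.unravel_index(g.argmax(), g.shape)
        center = (g.shape[0] // 2, g.shape[1] // 2)
        assert abs(peak[0] - center[0]) <= 4 and abs(peak[1] - center[1]) <= 4


class TestQuantileNormalization:
    def test_identical_grids_unchanged(self):
        cm = _embedded_cm(seed=2)
        for start in (40, 80, 120):  # every sample on the same coordinates
            cm.embedding[start:start + 40] = cm.embedding[:40]
        dg = estimate_density(cm, gridsize=20)
        out = quantile_normalize_grids(dg)
        assert np.allclose(out.grids["t1"], dg.grids["t1"], atol=1e-12)

    def test_sorted_vectors_equalized(self):
        dg = estimate_density(_embedded_cm(seed=4), gridsize=25)
        out = quantile_normalize_grids(dg)
        flats = [np.sort(g.ravel()) for g in out.grids.values()]
        for f in flats[1:]:
            assert np.allclose(f, flats[0])

    def test_monotone_transforms_collapse(self):
        dg = estimate_density(_embedded_cm(seed=5), gridsize=20)
        s0 = list(dg.grids)[0]
        for i, s in enumerate(list(dg.grids)[1:], start=2):
            dg.grids[s] = dg.grids[s0] ** i  # same ranks, different values
        out = quantile_normalize_grids(dg)
        for s in list(out.grids)[1:]:
            assert np.allclose(out.grids[s], out.grids[s0])


class TestDensityDiff:
    def test_identical_groups_zero_z(self):
        cm = _embedded_cm(seed=6)
        cm.embedding[80:] = cm.embedding[:80]  # normal copies tumor
        dg = quantile_normalize_grids(estimate_density(cm, gridsize=20))
        dm = density_diff(dg)
        assert np.allclose(dm.z[dm.mask], 0.0, atol=1e-8)

    def test_antisymmetric_under_label_swap(self):
        dg = quantile_normalize_grids(estimate_density(_embedded_cm(seed=7), gridsize=20))
        dm = density_diff(dg)
        swapped = {s: ("normal" if c == "tumor" else "tumor")
                   for s, c in dg.conditions.items()}
        dm2 = density_diff(dg, conditions=swapped)
        assert np.allclose(dm.z, -dm2.z, atol=1e-8)

    def test_empty_bins_masked(self):
        dm = density_diff(quantile_normalize_grids(
            estimate_density(_embedded_cm(seed=8), gridsize=25)))
        assert np.all(dm.z[~dm.mask] == 0.0)
        assert (~dm.mask).sum() > 0  # corners of the padded box are empty

    def test_planted_blob_found(self):
        # a dense cluster present only in tumor samples: the strongest
        # positive bin must fall inside the blob footprint
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = []
            for s in ("t1", "t2", "t3", "n1", "n2", "n3"):
                pts = rng.normal(0, 1, size=(60, 2))
                if s.startswith("t"):
                    pts[:20] = rng.normal([4, 4], 0.3, size=(20, 2))
                rows.append(pts)
            emb = np.vstack(rows)
            cmx = toy_cell_matrix(
                np.ones((2, 360), dtype=int),
                samples=np.repeat(["t1", "t2", "t3", "n1", "n2", "n3"], 60),
                conditions=np.repeat(["tumor"] * 3 + ["normal"] * 3, 60),
                embedding=emb)
            dg = quantile_normalize_grids(estimate_density(cmx, gridsize=30))
            dm = density_diff(dg)
            z = np.where(dm.mask, dm.z, -np.inf)
            i, j = np.unravel_index(np.argmax(z), z.shape)
            gx = np.linspace(dg.extent[0], dg.extent[1], dg.gridsize)
            gy = np.linspace(dg.extent[2], dg.extent[3], dg.gridsize)
            hits += (abs(gx[i] - 4) < 1.5) and (abs(gy[j] - 4) < 1.5)
        assert hits >= 19


class TestProportions:
    def test_parent_denominator_fraction(self):
        types = ["Macro-2"] * 4 + ["Macro-1"] * 6 + ["Tcell"] * 10
        cm = toy_cell_matrix(np.ones((2, 20), dtype=int), samples=["s1"] * 20,
                             cell_types=types)
        parent = {"Macro-2": "myeloid", "Macro-1": "myeloid", "Tcell": "lymphoid"}
        frac = celltype_fractions(cm, denominator="parent", parent_map=parent)
        assert frac.loc["s1", "Macro-2"] == pytest.approx(0.4)
        assert frac.loc["s1", "Tcell"] == pytest.approx(1.0)

    def test_identical_fraction_vectors_p_one(self):
        # 3 tumor and 3 normal samples with the same composition
        samples = np.repeat([f"s{i}" for i in range(6)], 10)
        conditions = np.repeat(["tumor"] * 3 + ["normal"] * 3, 10)
        types = np.tile(["a"] * 4 + ["b"] * 6, 6)
        cm = toy_cell_matrix(np.ones((2, 60), dtype=int), samples=samples,
                             conditions=conditions, cell_types=types)
        out = proportion_tests(cm)
        assert (out["p"] == 1.0).all()

    def test_adjusted_column_dominates(self, cm):
        out = proportion_tests(cm)
        ok = out.dropna(subset=["p"])
        assert (ok["p_adj"] >= ok["p"] - 1e-12).all()


class TestCoda:
    def test_uniform_composition_maps_to_zero(self):
        d = 5
        coords = clr(np.full((1, d), 1.0 / d)) @ ilr_basis(d).T
        assert np.allclose(coords, 0.0)

    def test_coefficients_sum_to_zero(self, cm, sample_conditions):
        counts = cm.obs.groupby(["sample", "cell_type"]).size().unstack(fill_value=0)
        res = coda_coefficients(counts, sample_conditions, n_boot=20,
                                cells_per_boot=200, seed=0)
        assert abs(res.coefficients.sum()) < 1e-8
        assert np.allclose(res.bootstrap_draws.sum(axis=1), 0.0, atol=1e-8)

    def test_basis_and_order_invariance(self, cm, sample_conditions):
        counts = cm.obs.groupby(["sample", "cell_type"]).size().unstack(fill_value=0)
        d = counts.shape[1]
        res1 = coda_coefficients(counts, sample_conditions, n_boot=2,
                                 cells_per_boot=100, seed=0)
        rot = ortho_group.rvs(d - 1, random_state=1)
        res2 = coda_coefficients(counts, sample_conditions, n_boot=2,
                                 cells_per_boot=100, seed=0,
                                 basis=rot @ helmert(d, full=False))
        assert np.allclose(res1.coefficients, res2.coefficients, atol=1e-8)
        perm = counts[list(counts.columns[::-1])]
        res3 = coda_coefficients(perm, sample_conditions, n_boot=2,
                                 cells_per_boot=100, seed=0)
        assert np.allclose(res1.coefficients[res3.coefficients.index],
                           res3.coefficients, atol=1e-8)

    def test_doubled_type_gets_positive_coefficient(self):
        cmx, _ = simulate_cohort(small_config(
            n_samples_per_condition=8, cells_mean=250, n_genes=30,
            composition_effects={"macrophage": 2.0}, seed=31))
        counts = cmx.obs.groupby(["sample", "cell_type"]).size().unstack(fill_value=0)
        cond = cmx.obs.groupby("sample")["condition"].agg(lambda s: s.mode().iat[0])
        res = coda_coefficients(counts, cond, n_boot=200, cells_per_boot=500, seed=2)
        assert res.coefficients["macrophage"] > 0
        assert (res.bootstrap_draws["macrophage"] > 0).mean() >= 0.95

    def test_too_few_samples_rejected(self):
        counts = pd.DataFrame([[5, 5]] * 4, index=["a", "b", "c", "d"],
                              columns=["x", "y"])
        cond = pd.Series(["tumor", "tumor", "normal", "normal"],
                         index=counts.index)
        with pytest.raises(ValueError, match="3 samples"):
            coda_coefficients(counts, cond, n_boot=2, cells_per_boot=10, seed=0)
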