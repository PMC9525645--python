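from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scduet import normalize
from scduet.data import NormalizedMatrix
from scduet.interactions import (LRPairTable, condition_filter, permutation_test,
                                 read_lr_pairs, score_pairs, screen_pairs,
                                 specificity_filter)
from scduet.markers import marker_genes
from scduet.simulate import LRPlant, simulate_cohort

from conftest import small_config, toy_cell_matrix


def _nm(values, cell_types):
    cm = toy_cell_matrix(np.zeros_like(np.asarray(values)),
                         cell_types=list(cell_types))
    return NormalizedMatrix(
        values=sp.csc_matrix(np.asarray(values, dtype=float)),
        gene_ids=cm.gene_ids, cell_ids=cm.cell_ids, obs=cm.obs, embedding=None,
    )


def _pairs(*pairs):
    return LRPairTable(pd.DataFrame(
        [{"ligand": l, "receptor": r, "pair_id": f"{l}_{r}"} for l, r in pairs]))


class TestScreen:
    def test_expression_fraction_boundaries(self):
        # g0: 5% of senders; g1: exactly 10%; g2: 50% -- only >10% passes
        n = 20
        vals = np.zeros((4, 2 * n))
        vals[0, :1] = 1.0                 # 5% of type A
        vals[1, : n // 10] = 1.0          # exactly 10% of A
        vals[2, : n // 2] = 1.0           # 50% of A
        vals[3, n:] = 1.0                 # receptor in 100% of B
        nm = _nm(vals, ["A"] * n + ["B"] * n)
        out = screen_pairs(nm, _pairs(("g0", "g3"), ("g1", "g3"), ("g2", "g3")))
        kept = set(zip(out["ligand"], out["sender"]))
        assert ("g0", "A") not in kept
        assert ("g1", "A") not in kept    # strict inequality at the boundary
        assert ("g2", "A") in kept

    def test_absent_gene_drops_pair(self):
        vals = np.ones((2, 10))
        nm = _nm(vals, ["A"] * 5 + ["B"] * 5)
        out = screen_pairs(nm, _pairs(("g0", "NOT_THERE"), ("g0", "g1")))
        assert set(out["pair_id"]) == {"g0_g1"}


class TestScore:
    def test_product_of_means(self):
        vals = np.zeros((2, 4))
        vals[0, :2] = 2.0   # ligand mean 2 in A
        vals[1, 2:] = 3.0   # receptor mean 3 in B
        nm = _nm(vals, ["A", "A", "B", "B"])
        cands = pd.DataFrame([{"pair_id": "p", "ligand": "g0", "receptor": "g1",
                               "sender": "A", "receiver": "B"}])
        assert score_pairs(nm, cands)["score"].iloc[0] == pytest.approx(6.0)

    def test_zero_ligand_zero_score(self):
        vals = np.zeros((2, 4))
        vals[1, 2:] = 3.0
        nm = _nm(vals, ["A", "A", "B", "B"])
        cands = pd.DataFrame([{"pair_id": "p", "ligand": "g0", "receptor": "g1",
                               "sender": "A", "receiver": "B"}])
        assert score_pairs(nm, cands)["score"].iloc[0] == 0.0

    def test_role_asymmetry(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(1.0, 1.0, size=(2, 12))
        nm = _nm(vals, ["A"] * 6 + ["B"] * 6)
        base = pd.DataFrame([{"pair_id": "p", "ligand": "g0", "receptor": "g1",
                              "sender": "A", "receiver": "B"}])
        swapped_roles = base.assign(sender="B", receiver="A")
        both_swapped = base.assign(ligand="g1", receptor="g0",
                                   sender="B", receiver="A")
        s0 = score_pairs(nm, base)["score"].iloc[0]
        s1 = score_pairs(nm, swapped_roles)["score"].iloc[0]
        s2 = score_pairs(nm, both_swapped)["score"].iloc[0]
        assert s0 != pytest.approx(s1)
        # swapping ligand/receptor AND sender/receiver recovers the product
        assert s0 == pytest.approx(s2)


class TestPermutation:
    def test_identical_cells_p_one(self):
        vals = np.ones((2, 10))
        nm = _nm(vals, ["A"] * 5 + ["B"] * 5)
        cands = screen_pairs(nm, _pairs(("g0", "g1")))
        out = permutation_test(nm, cands, n_perm=50, seed=0)
        assert (out["p"] == 1.0).all()

    def test_six_cell_toy_matches_enumeration(self):
        rng = np.random.default_rng(5)
        vals = rng.gamma(2.0, 1.0, size=(2, 6))
        types = ["A", "A", "A", "B", "B", "B"]
        nm = _nm(vals, types)
        cands = pd.DataFrame([{"pair_id": "p", "ligand": "g0", "receptor": "g1",
                               "sender": "A", "receiver": "B"}])
        obs = score_pairs(nm, cands)["score"].iloc[0]
        # oracle: enumerate all C(6,3)=20 assignments of cells to type A
        hits = total = 0
        for idx in combinations(range(6), 3):
            a = list(idx)
            b = [i for i in range(6) if i not in idx]
            total += 1
            hits += vals[0, a].mean() * vals[1, b].mean() >= obs - 1e-12
        p_enum = hits / total
        n_perm = 2000
        out = permutation_test(nm, cands, n_perm=n_perm, seed=1)
        assert abs(out["p"].iloc[0] - p_enum) <= 1.0 / np.sqrt(n_perm)

    def test_seeded_determinism_and_order_invariance(self):
        cmx, _ = simulate_cohort(small_config(
            n_samples_per_condition=2, cells_mean=100, n_genes=40, seed=3))
        nm = normalize(cmx)
        cands = screen_pairs(nm, _pairs(("G0001", "G0002"), ("G0003", "G0004")))
        a = permutation_test(nm, cands, n_perm=100, seed=9)
        b = permutation_test(nm, cands, n_perm=100, seed=9)
        assert a["p"].tolist() == b["p"].tolist()
        # permuting cell order leaves the p-values unchanged
        rng = np.random.default_rng(0)
        perm = rng.permutation(cmx.n_cells)
        nm2 = normalize(cmx.subset(perm))
        c = permutation_test(nm2, screen_pairs(nm2, _pairs(("G0001", "G0002"),
                                                           ("G0003", "G0004"))),
                             n_perm=100, seed=9)
        merged = a.merge(c, on=["pair_id", "sender", "receiver"])
        assert np.allclose(merged["score_x"], merged["score_y"])

    def test_planted_coelevation_detected(self):
        cmx, _ = simulate_cohort(small_config(
            n_samples_per_condition=3, cells_mean=250, n_genes=150, seed=7,
            lr_plants=[LRPlant("G0100", "macrophage", "G0101", "tcell", 4.0)]))
        nm = normalize(cmx)
        decoys = [(f"G{i:04d}", f"G{i + 1:04d}") for i in range(110, 130, 2)]
        cands = screen_pairs(nm, _pairs(("G0100", "G0101"), *decoys))
        out = permutation_test(nm, cands, n_perm=500, seed=2)
        hit = out[(out["pair_id"] == "G0100_G0101")
                  & (out["sender"] == "macrophage") & (out["receiver"] == "tcell")]
        assert hit["p_adj"].iloc[0] < 0.05


class TestFilters:
    def test_uniform_ligand_dropped_exclusive_kept(self):
        vals = np.zeros((3, 40))
        vals[0, :] = 1.0          # uniform ligand
        vals[1, :20] = 5.0        # exclusive ligand in A
        vals[2, 20:] = 5.0        # exclusive receptor in B
        nm = _nm(vals, ["A"] * 20 + ["B"] * 20)
        mt = marker_genes(nm, nm.obs["cell_type"])
        cands = pd.DataFrame([
            {"pair_id": "u", "ligand": "g0", "receptor": "g2",
             "sender": "A", "receiver": "B"},
            {"pair_id": "x", "ligand": "g1", "receptor": "g2",
             "sender": "A", "receiver": "B"},
        ])
        out = specificity_filter(mt, cands, z_min=3.0)
        assert set(out["pair_id"]) == {"x"}
        assert len(specificity_filter(mt, cands, z_min=np.inf)) == 0

    def test_condition_filter_modes_and_boundary(self):
        cands = pd.DataFrame([{"pair_id": "p", "ligand": "L", "receptor": "R",
                               "sender": "A", "receiver": "B"}])
        de = lambda lfc_l, lfc_r: {
            "A": pd.DataFrame({"gene": ["L"], "log2FoldChange": [lfc_l]}),
            "B": pd.DataFrame({"gene": ["R"], "log2FoldChange": [lfc_r]}),
        }
        assert len(condition_filter(de(-0.5, 0.5), cands, mode="both")) == 0
        assert len(condition_filter(de(-0.5, 0.5), cands, mode="either")) == 1
        assert len(condition_filter(de(0.0, 0.0), cands, mode="both")) == 0
        assert len(condition_filter(de(0.3, 0.4), cands, mode="both")) == 1

    def test_missing_de_table_drops_triples(self):
        cands = pd.DataFrame([{"pair_id": "p", "ligand": "L", "receptor": "R",
                               "sender": "A", "receiver": "B"}])
        tables = {"A": pd.DataFrame({"gene": ["L"], "log2FoldChange": [1.0]})}
        assert len(condition_filter(tables, cands)) == 0


def test_read_lr_pairs_formats(tmp_path):
    p = tmp_path / "pairs.tsv"
    p.write_text("ligand\treceptor\nCD70\tCD27\nCXCL9\tCXCR3\n")
    table = read_lr_pairs(p)
    assert len(table.pairs) == 2
    assert set(table.pairs["pair_id"]) == {"CD70_CD27", "CXCL9_CXCR3"}
    headerless = tmp_path / "plain.tsv"
    headerless.write_text("SPP1\tITGB1\n")
    assert read_lr_pairs(headerless).pairs["ligand"].iloc[0] == "SPP1"
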