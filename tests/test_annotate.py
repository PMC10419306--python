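import math

import numpy as np
import pytest
from scipy import sparse

from scstate.annotate import NormalizedMatrix, annotate_clusters, coexpression_gate, log_normalize, marker_auc
from scstate.io_formats import CountMatrix


def norm_from_rows(rows, genes):
    rows = np.asarray(rows, dtype=float)
    return NormalizedMatrix(
        genes=genes,
        barcodes=[f"c{i}" for i in range(rows.shape[1])],
        values=sparse.csc_matrix(rows),
    )


class TestLogNormalize:
    def test_zero_count_maps_to_zero(self):
        m = CountMatrix(["g1", "g2"], ["c1"], sparse.csc_matrix(np.array([[0], [7]])))
        out = log_normalize(m)
        assert out.values[0, 0] == 0.0

    def test_closed_form_single_count(self):
        col = np.zeros((10000, 1), dtype=int)
        col[:, 0] = 1
        m = CountMatrix([f"g{i}" for i in range(10000)], ["c1"], sparse.csc_matrix(col))
        out = log_normalize(m, scale_factor=10000)
        assert out.values[0, 0] == pytest.approx(math.log(2), abs=1e-12)

    def test_all_zero_cell_stays_zero(self):
        m = CountMatrix(["g1"], ["c1", "c2"], sparse.csc_matrix(np.array([[0, 3]])))
        out = log_normalize(m)
        assert out.values[:, 0].nnz == 0

    def test_within_cell_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(50, 4))
        m = CountMatrix([f"g{i}" for i in range(50)], [f"c{i}" for i in range(4)], sparse.csc_matrix(counts))
        out = np.asarray(log_normalize(m).values.todense())
        for j in range(4):
            assert (np.argsort(counts[:, j], kind="stable") == np.argsort(out[:, j], kind="stable")).all()


class TestAnnotateClusters:
    def test_dominant_marker_expression_wins(self):
        norm = norm_from_rows([[2.0, 0.0], [0.0, 2.0]], genes=["mA", "mB"])
        assignment, scores = annotate_clusters(norm, [0, 1], {"A": ["mA"], "B": ["mB"]})
        assert assignment == {0: "A", 1: "B"}
        assert not scores["tie"].any()

    def test_exact_tie_goes_to_first_declared_label(self):
        norm = norm_from_rows([[1.0], [1.0]], genes=["mA", "mB"])
        assignment, scores = annotate_clusters(norm, [0], {"B": ["mB"], "A": ["mA"]})
        assert assignment == {0: "B"}
        assert scores["tie"].all()

    def test_simulated_clusters_all_recover_their_true_type(self, sim_run, sim_norm):
        cfg, _, cells, _ = sim_run
        assignment, _ = annotate_clusters(sim_norm, cells["cluster"].to_numpy(), cfg.markers)
        types = cfg.cell_types
        assert all(assignment[i] == types[i] for i in assignment)

    def test_empty_input_is_an_error(self):
        norm = norm_from_rows([[1.0]], genes=["mA"])
        with pytest.raises(ValueError):
            annotate_clusters(norm, [], {"A": ["mA"]})


class TestCoexpressionGate:
    def test_double_positive_flagged_single_positive_not(self):
        norm = norm_from_rows([[1.0, 1.0, 0.0], [0.5, 0.0, 0.0]], genes=["TBX21", "RUNX1"])
        assert coexpression_gate(norm, "TBX21", "RUNX1").tolist() == [True, False, False]

    def test_missing_gene_error_names_the_gene(self):
        norm = norm_from_rows([[1.0]], genes=["TBX21"])
        with pytest.raises(KeyError, match="RUNX1"):
            coexpression_gate(norm, "TBX21", "RUNX1")

    def test_gate_invariant_to_normalization(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(0.5, size=(5, 40))
        m = CountMatrix([f"g{i}" for i in range(5)], [f"c{i}" for i in range(40)], sparse.csc_matrix(counts))
        raw = NormalizedMatrix(m.genes, m.barcodes, m.counts.astype(float))
        assert (
            coexpression_gate(log_normalize(m), "g0", "g1")
            == coexpression_gate(raw, "g0", "g1")
        ).all()


class TestMarkerAuc:
    def test_perfect_separation_scores_one(self):
        norm = norm_from_rows([[2.0, 3.0, 0.0, 0.0]], genes=["g"])
        assert marker_auc(norm, [True, True, False, False], "g") == 1.0

    def test_constant_gene_scores_half(self):
        norm = norm_from_rows([[1.0, 1.0, 1.0, 1.0]], genes=["g"])
        assert marker_auc(norm, [True, False, True, False], "g") == 0.5

    def test_small_instance_matches_exhaustive_pair_counting(self):
        # positives {2,3,4} vs negatives {1,2,3}: wins 1+0.5, 2+0.5, 3 -> U=7
        norm = norm_from_rows([[2.0, 3.0, 4.0, 1.0, 2.0, 3.0]], genes=["g"])
        mask = [True, True, True, False, False, False]
        assert marker_auc(norm, mask, "g") == pytest.approx(7 / 9)

    def test_degenerate_mask_is_an_error(self):
        norm = norm_from_rows([[1.0, 2.0]], genes=["g"])
        with pytest.raises(ValueError, match="degenerate"):
            marker_auc(norm, [True, True], "g")

    def test_label_swap_complements_the_auc(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=30)
        norm = norm_from_rows([vals], genes=["g"])
        mask = rng.random(30) < 0.4
        if not mask.any() or mask.all():
            mask[0] = True
            mask[1] = False
        a = marker_auc(norm, mask, "g")
        b = marker_auc(norm, ~mask, "g")
        assert a + b == pytest.approx(1.0)

    def test_planted_subtype_frequency_within_binomial_ci(self, sim_run, sim_norm):
        cfg, _, cells, truth = sim_run
        gated = coexpression_gate(sim_norm, "TBX21", "RUNX1")
        parent = (cells["cell_type"] == "T_cell") & (cells["condition"] == "disease")
        n, k = int(parent.sum()), int(gated[parent.to_numpy()].sum())
        p0 = cfg.subtype.frequency["disease"]
        half = 1.96 * math.sqrt(p0 * (1 - p0) / n)
        assert abs(k / n - p0) <= half
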