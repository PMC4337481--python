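"""Spearman correlation, edge weight/delta arithmetic, and the
label-permutation filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfregnet.io_formats import EdgeList
from tfregnet.network_weighting import (RegulatoryEdge, permutation_filter,
                                        spearman_rho, weight_edges)
from tfregnet.synthetic import SimulationConfig, simulate_dataset

from conftest import make_matrix
from oracles import spearman_oracle


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_perfect_antimonotone(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_hand_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        assert spearman_rho(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_vector_defined_as_zero(self):
        assert spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]) == 0.0

    @pytest.mark.parametrize("x,y", [([1, 2], [1, 2]), ([1, 2, 3], [1, 2])])
    def test_bad_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            spearman_rho(x, y)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, 3 * y + 7) == pytest.approx(base, abs=1e-12)


class TestWeightEdges:
    def _matrix_with_rhos(self):
        # 40+40 samples, TF plus targets at controlled correlations
        rng = np.random.default_rng(0)
        n = 80
        tf = rng.normal(size=n)
        rows = [tf]
        for rho1, rho2 in [(0.8, 0.8), (0.6, -0.6), (0.9, 0.3)]:
            eps = rng.normal(size=n)
            z = np.empty(n)
            z[:40] = rho1 * tf[:40] + np.sqrt(1 - rho1 ** 2) * eps[:40]
            z[40:] = rho2 * tf[40:] + np.sqrt(1 - rho2 ** 2) * eps[40:]
            rows.append(z)
        return make_matrix(np.array(rows), gene_ids=["TF", "A", "B", "C"],
                           groups=(40, 40))

    def test_weight_and_delta_formulas(self):
        m = self._matrix_with_rhos()
        edges = weight_edges(m, EdgeList(edges=(("TF", "A"), ("TF", "B"), ("TF", "C"))))
        for e in edges:
            assert e.weight == pytest.approx(abs(e.r_group1 + e.r_group2) / 2, abs=1e-15)
            assert e.delta == pytest.approx(abs(e.r_group1 - e.r_group2) / 2, abs=1e-15)
            assert e.weight + e.delta <= 1.0 + 1e-12

    def test_matches_scalar_spearman(self):
        m = self._matrix_with_rhos()
        edges = weight_edges(m, EdgeList(edges=(("TF", "A"),)))
        vals = m.values.to_numpy()
        g1 = m.group_columns(m.groups[0])
        g2 = m.group_columns(m.groups[1])
        assert edges[0].r_group1 == pytest.approx(
            spearman_rho(vals[0, g1], vals[1, g1]), abs=1e-12)
        assert edges[0].r_group2 == pytest.approx(
            spearman_rho(vals[0, g2], vals[1, g2]), abs=1e-12)

    def test_absent_genes_dropped_and_empty_errors(self, small_matrix):
        edges = weight_edges(small_matrix,
                             EdgeList(edges=(("G0", "G1"), ("G0", "NOPE"))))
        assert len(edges) == 1
        with pytest.raises(ValueError, match="no edges"):
            weight_edges(small_matrix, EdgeList(edges=(("X", "Y"),)))

    def test_label_swap_leaves_weight_and_delta_unchanged(self):
        rng = np.random.default_rng(4)
        values = 8 + rng.standard_normal((5, 16))
        edge_list = EdgeList(edges=(("G0", "G1"), ("G2", "G3")))
        a = weight_edges(make_matrix(values, groups=(8, 8), labels=("a", "b")),
                         edge_list)
        b = weight_edges(make_matrix(values, groups=(8, 8), labels=("b", "a")),
                         edge_list)
        for ea, eb in zip(a, b):
            assert ea.weight == pytest.approx(eb.weight, abs=1e-12)
            assert ea.delta == pytest.approx(eb.delta, abs=1e-12)


class TestPermutationFilter:
    def test_duplicated_group_means_nothing_passes(self):
        # group 2 an exact copy of group 1: all deltas are 0
        rng = np.random.default_rng(2)
        half = 8 + rng.standard_normal((6, 10))
        values = np.concatenate([half, half], axis=1)
        m = make_matrix(values, groups=(10, 10))
        edges = weight_edges(m, EdgeList(edges=(("G0", "G1"), ("G2", "G3"))))
        assert all(e.delta == pytest.approx(0.0, abs=1e-12) for e in edges)
        net = permutation_filter(m, edges, n_permutations=100, seed=1)
        assert len(net.passing_edges) == 0

    def test_planted_differential_edges_pass(self):
        cfg = SimulationConfig(seed=31, n_group1=30, n_group2=30, n_genes=200,
                               n_tfs=5, targets_per_tf=(20, 20),
                               n_planted_diffcoreg_tfs=1,
                               planted_rho_group1=0.8, planted_rho_group2=-0.2,
                               n_planted_degs=0)
        matrix, edge_list, truth = simulate_dataset(cfg)
        edges = weight_edges(matrix, edge_list)
        net = permutation_filter(matrix, edges, n_permutations=200, seed=7)
        planted = {(tf, tgt) for (tf, tgt) in truth.edge_rho
                   if tf in truth.true_diffcoreg_tf_ids}
        passing = {e.edge_id for e in net.passing_edges}
        assert len(passing & planted) / len(planted) >= 0.9

    def test_threshold_monotone_in_quantile(self, small_matrix):
        edges = weight_edges(small_matrix,
                             EdgeList(edges=(("G0", "G1"), ("G2", "G3"),
                                             ("G4", "G5"), ("G0", "G2"))))
        n_pass = []
        for q in (0.5, 0.7, 0.9):
            net = permutation_filter(small_matrix, edges, n_permutations=100,
                                     quantile=q, seed=3)
            n_pass.append(len(net.passing_edges))
        assert n_pass[0] >= n_pass[1] >= n_pass[2]

    def test_drop_above_is_complement(self, small_matrix):
        edges = weight_edges(small_matrix,
                             EdgeList(edges=(("G0", "G1"), ("G2", "G3"))))
        keep = permutation_filter(small_matrix, edges, n_permutations=100,
                                  mode="keep_above", seed=5)
        drop = permutation_filter(small_matrix, edges, n_permutations=100,
                                  mode="drop_above", seed=5)
        assert {e.edge_id for e in keep.passing_edges}.isdisjoint(
            {e.edge_id for e in drop.passing_edges})
        assert len(keep.passing_edges) + len(drop.passing_edges) == len(edges)

    def test_seed_determinism(self, small_matrix):
        edges = weight_edges(small_matrix, EdgeList(edges=(("G0", "G1"),)))
        a = permutation_filter(small_matrix, edges, n_permutations=100, seed=11)
        b = permutation_filter(small_matrix, edges, n_permutations=100, seed=11)
        assert a.permutation_threshold == b.permutation_threshold

    @pytest.mark.parametrize("kwargs", [dict(quantile=0.0), dict(quantile=1.2),
                                        dict(n_permutations=5),
                                        dict(mode="sideways")])
    def test_bad_parameters_rejected(self, small_matrix, kwargs):
        edges = weight_edges(small_matrix, EdgeList(edges=(("G0", "G1"),)))
        params = dict(n_permutations=100, quantile=0.9, mode="keep_above", seed=0)
        params.update(kwargs)
        with pytest.raises(ValueError):
            permutation_filter(small_matrix, edges, **params)

    def test_degrees_consistent_with_passing_edges(self):
        cfg = SimulationConfig(seed=8, n_group1=10, n_group2=10, n_genes=100,
                               n_tfs=4, targets_per_tf=(10, 10), n_planted_degs=0)
        matrix, edge_list, _ = simulate_dataset(cfg)
        edges = weight_edges(matrix, edge_list)
        net = permutation_filter(matrix, edges, n_permutations=100, seed=1)
        manual = {}
        for e in net.passing_edges:
            manual[e.tf_id] = manual.get(e.tf_id, 0) + 1
        assert net.degrees() == manual
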