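"""Scaled-delta adjacency, TOM, module detection and signed connectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from diffconet.network import (
    DifferentialNetwork,
    delta_matrix_from_edges,
    detect_modules,
    hub_nodes,
    largest_component,
    scale_delta_matrix,
    signed_connectivity,
    topological_overlap,
)


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Index-loop TOM: (sum_u a_iu*a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    n = a.shape[0]
    k = [sum(a[i, u] for u in range(n)) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def edge_frame(rows):
    """rows: (gene_a, gene_b, delta, significant[, r_R, r_S])."""
    recs = []
    for row in rows:
        a, b, d, sig = row[:4]
        r_r, r_s = (row[4], row[5]) if len(row) > 4 else (0.0, 0.0)
        recs.append(
            dict(gene_a=a, gene_b=b, delta=d, significant=sig, r_R=r_r, r_S=r_s,
                 z_R=0.0, z_S=0.0, p_value=0.5, lfdr=0.5, sign=int(np.sign(d)))
        )
    return pd.DataFrame(recs)


class TestScaleDelta:
    def test_zero_matrix(self):
        assert not scale_delta_matrix(np.zeros((4, 4))).any()

    def test_max_maps_to_one(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = -4.0
        d[1, 2] = d[2, 1] = 2.0
        a = scale_delta_matrix(d)
        assert a[0, 1] == 1.0 and a[1, 2] == 0.5
        assert np.all(np.diag(a) == 0.0)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0, 2, (6, 6))
        d = d + d.T
        np.fill_diagonal(d, 0.0)
        a = scale_delta_matrix(d)
        m = np.abs(d).max()
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else abs(d[i, j]) / m
                assert a[i, j] == pytest.approx(expected, abs=1e-14)

    def test_rejects_asymmetric(self):
        d = np.zeros((3, 3))
        d[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            scale_delta_matrix(d)


class TestTopologicalOverlap:
    def test_unit_triangle_is_one(self):
        a = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(topological_overlap(a), 1.0)

    def test_three_node_path(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1.0
        tom = topological_overlap(a)
        assert tom[0, 2] == pytest.approx(0.5)  # (1 + 0) / (1 + 1 - 0)

    def test_empty_graph(self):
        tom = topological_overlap(np.zeros((5, 5)))
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_exhaustive_small_graph_oracle(self):
        """All weighted graphs on 2-4 nodes with weights in {0, 0.5, 1}."""
        from itertools import product

        weights = (0.0, 0.5, 1.0)
        for n in (2, 3, 4):
            iu = np.triu_indices(n, k=1)
            for combo in product(weights, repeat=len(iu[0])):
                a = np.zeros((n, n))
                a[iu] = combo
                a = a + a.T
                assert np.allclose(topological_overlap(a), tom_oracle(a), atol=1e-12)

    def test_five_node_sample_oracle(self):
        rng = np.random.default_rng(17)
        iu = np.triu_indices(5, k=1)
        for _ in range(500):
            a = np.zeros((5, 5))
            a[iu] = rng.choice([0.0, 0.5, 1.0], size=10)
            a = a + a.T
            assert np.allclose(topological_overlap(a), tom_oracle(a), atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(arrays(np.float64, (6, 6), elements=st.floats(0, 1)))
    def test_range_and_symmetry_property(self, raw):
        a = (raw + raw.T) / 2.0
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        assert np.allclose(tom, tom.T)
        assert np.all((tom >= 0.0) & (tom <= 1.0))

    def test_rejects_out_of_range(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            topological_overlap(a)


class TestDetectModules:
    def test_two_disconnected_cliques(self):
        a = np.zeros((20, 20))
        a[:10, :10] = 1.0
        a[10:, 10:] = 1.0
        np.fill_diagonal(a, 0.0)
        labels = detect_modules(topological_overlap(a), min_module_size=5)
        assert len(set(labels)) == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert set(labels) == {1, 2}

    def test_identity_tom_all_unassigned(self):
        labels = detect_modules(np.eye(12), min_module_size=3)
        assert set(labels) == {0}

    def test_fixed_k_cut(self):
        a = np.zeros((20, 20))
        a[:10, :10] = 1.0
        a[10:, 10:] = 1.0
        np.fill_diagonal(a, 0.0)
        labels = detect_modules(
            topological_overlap(a), min_module_size=5, method="fixed_k", n_modules=2
        )
        assert len(set(labels)) == 2

    def test_tiny_input_single_module(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            labels = detect_modules(np.eye(2), min_module_size=5)
        assert labels.tolist() == [1, 1]


class TestSignedConnectivity:
    def test_hand_arithmetic(self):
        # intramodular weights +0.5, +0.3, -0.2 at node "a" via r_diff weights
        edges = edge_frame(
            [
                ("a", "b", 1.0, True, 0.5, 0.0),
                ("a", "c", 1.0, True, 0.3, 0.0),
                ("a", "d", -1.0, True, 0.0, 0.2),
            ]
        )
        labels = pd.Series(1, index=["a", "b", "c", "d"])
        kw = signed_connectivity(edges, labels, weight_mode="r_diff")
        assert kw["a"] == pytest.approx(0.8 - 0.2)

    def test_no_intramodular_edges_is_zero(self):
        edges = edge_frame([("a", "b", 2.0, True)])
        labels = pd.Series([1, 2, 2], index=["a", "b", "c"])
        kw = signed_connectivity(edges, labels)
        assert kw["a"] == 0.0 and kw["c"] == 0.0

    def test_scaled_delta_weights_use_global_max(self):
        edges = edge_frame([("a", "b", 2.0, True), ("c", "d", -4.0, False)])
        labels = pd.Series(1, index=["a", "b", "c", "d"])
        kw = signed_connectivity(edges, labels)
        assert kw["a"] == pytest.approx(0.5)  # 2 / max|delta| = 2/4
        assert kw["c"] == 0.0  # non-significant edge excluded

    def test_brute_force_oracle_random_module(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:02d}" for i in range(15)]
        rows = []
        for i in range(15):
            for j in range(i + 1, 15):
                if rng.random() < 0.4:
                    rows.append((genes[i], genes[j], rng.normal(0, 2), rng.random() < 0.8))
        edges = edge_frame(rows)
        labels = pd.Series(rng.choice([1, 2], size=15), index=genes)
        kw = signed_connectivity(edges, labels)
        max_abs = edges["delta"].abs().max()
        expected = dict.fromkeys(genes, 0.0)
        for row in edges.itertuples(index=False):
            if not row.significant or labels[row.gene_a] != labels[row.gene_b]:
                continue
            w = row.delta / max_abs
            for g in (row.gene_a, row.gene_b):
                expected[g] += w if w >= 0 else -abs(w)  # conn+ minus |conn-|
        for g in genes:
            assert kw[g] == pytest.approx(expected[g], abs=1e-12)

    def test_additive_over_edge_subsets(self):
        """kWithin is linear: per-edge contributions at a fixed weight scale add up."""
        edges = edge_frame(
            [("a", "b", 1.0, True), ("a", "c", -2.0, True), ("a", "d", 4.0, True)]
        )
        labels = pd.Series(1, index=["a", "b", "c", "d"])
        whole = signed_connectivity(edges, labels)
        parts = sum(_weighted(edges.iloc[[i]], labels) for i in range(3))
        assert whole["a"] == pytest.approx(parts["a"])
        assert whole["a"] == pytest.approx((1.0 - 2.0 + 4.0) / 4.0)

    def test_unlabeled_endpoint_errors(self):
        edges = edge_frame([("a", "zz", 1.0, True)])
        labels = pd.Series(1, index=["a"])
        with pytest.raises(ValueError, match="zz"):
            signed_connectivity(edges, labels)


def _weighted(edges, labels):
    """Per-edge kWithin contribution at the FULL table's weight scale (4.0)."""
    out = pd.Series(0.0, index=labels.index)
    for row in edges.itertuples(index=False):
        w = row.delta / 4.0
        out[row.gene_a] += w if w >= 0 else -abs(w)
        out[row.gene_b] += w if w >= 0 else -abs(w)
    return out


def _network_from(edges, genes):
    d = delta_matrix_from_edges(edges, genes)
    return DifferentialNetwork(
        genes=genes,
        adjacency=scale_delta_matrix(d),
        edges=edges[edges["significant"]].reset_index(drop=True),
        all_edges=edges,
    )


class TestLargestComponent:
    def test_single_clique_module(self):
        genes = ["a", "b", "c"]
        edges = edge_frame([("a", "b", 1, True), ("b", "c", 1, True), ("a", "c", 1, True)])
        net = _network_from(edges, genes)
        labels = pd.Series(1, index=genes)
        assert largest_component(net, labels, 1) == {"a", "b", "c"}

    def test_two_components_takes_larger(self):
        genes = list("abcdefgh")
        edges = edge_frame(
            [("a", "b", 1, True), ("b", "c", 1, True), ("c", "d", 1, True),
             ("d", "e", 1, True), ("f", "g", 1, True), ("g", "h", 1, True)]
        )
        net = _network_from(edges, genes)
        labels = pd.Series(1, index=genes)
        assert largest_component(net, labels, 1) == {"a", "b", "c", "d", "e"}

    def test_module_without_edges_warns_empty(self):
        genes = ["a", "b", "c"]
        edges = edge_frame([("a", "b", 1, True)])
        net = _network_from(edges, genes)
        labels = pd.Series([1, 1, 2], index=genes)
        with pytest.warns(UserWarning, match="no significant edges"):
            assert largest_component(net, labels, 2) == set()
        with pytest.raises(ValueError, match="does not exist"):
            largest_component(net, labels, 9)


def test_planted_hub_recovery_across_seeds():
    """Planted hubs rank in their module's top 20% by kWithin in >= 8/10 seeds.

    Full pipeline on 3 differential modules whose first gene carries a
    boosted factor loading (the planted hub); recovery requires both the
    module partition (ARI >= 0.8) and the hub ranking to come out.
    """
    from sklearn.metrics import adjusted_rand_score

    from diffconet.diffcorr import build_edge_table, correlation_matrix
    from diffconet.synthetic import SyntheticSpec, generate_expression_pair

    good = 0
    for seed in range(10):
        spec = SyntheticSpec(
            n_genes=120,
            module_sizes=[40, 40, 40],
            rho_R=[0.8, 0.8, 0.8],
            rho_S=[0.0, 0.0, 0.0],
            hub_rho=[0.95, 0.95, 0.95],
            n_samples_R=50,
            n_samples_S=50,
            seed=100 + seed,
        )
        expr_r, expr_s, truth = generate_expression_pair(spec)
        edges, _ = build_edge_table(correlation_matrix(expr_r), correlation_matrix(expr_s))
        dmat = delta_matrix_from_edges(edges, list(expr_r.index))
        labels = pd.Series(
            detect_modules(topological_overlap(scale_delta_matrix(dmat)), 20),
            index=expr_r.index,
        )
        if adjusted_rand_score(truth.labels.to_numpy(), labels.to_numpy()) < 0.8:
            continue
        kwithin = signed_connectivity(edges, labels)
        hubs_ok = True
        for hub in truth.hub_genes.values():
            module = labels.index[labels == labels[hub]]
            rank = kwithin[module].rank(ascending=False)[hub]
            if rank > 0.2 * len(module):
                hubs_ok = False
        good += hubs_ok
    assert good >= 8


class TestHubNodes:
    def test_ranking_and_ties(self):
        kw = pd.Series({"a": 0.6, "b": 0.2})
        assert hub_nodes(kw, 1) == ["a"]
        tied = pd.Series({"z": 1.0, "a": 1.0, "m": 1.0})
        assert hub_nodes(tied, 3) == ["a", "m", "z"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(21)
        kw = pd.Series(rng.normal(size=40), index=[f"g{i:02d}" for i in range(40)])
        expected = [g for g, _ in sorted(kw.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert hub_nodes(kw, 40) == expected
        assert hub_nodes(kw, 5) == expected[:5]
        with pytest.raises(ValueError, match="top_n"):
            hub_nodes(kw, 0)
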