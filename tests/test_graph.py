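"""All-paths graph kernel: construction, Neumann closed form, Gram PSD."""

import numpy as np
import pytest

from lbdkit.graph import (
    GraphKernelError,
    KernelConfig,
    LabeledGraph,
    build_graph,
    cross_gram,
    gram_matrix,
    graph_matrix,
    kernel_value,
)

from conftest import make_sentence


# ---------------------------------------------------------------------------
# Independent oracle: truncated walk-sum, evaluated by accumulating powers
# of the edge matrix.  With spectral radius <= 0.8 a truncation length of
# 150 bounds the geometric tail far below 1e-9.

def walk_sum_oracle(g: LabeledGraph, max_len: int = 150):
    A = g.edge_matrix()
    n = g.n_vertices
    W = np.zeros((n, n))
    P = np.eye(n)
    for _ in range(max_len):
        P = P @ A
        W += P
    entries = {}
    for u in range(n):
        for v in range(n):
            if W[u, v] == 0:
                continue
            for a in g.labels[u]:
                for b in g.labels[v]:
                    entries[(a, b)] = entries.get((a, b), 0.0) + W[u, v]
    return entries


def random_graph(rng, max_vertices=6, alphabet="abcd"):
    n = int(rng.integers(2, max_vertices + 1))
    labels = [
        frozenset(rng.choice(list(alphabet),
                             size=int(rng.integers(1, 3)), replace=False))
        for _ in range(n)
    ]
    edges = {}
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.4:
                edges[(i, j)] = float(rng.uniform(0.05, 0.9))
    g = LabeledGraph(labels=labels, edges=edges, graph_id="rand")
    A = g.edge_matrix()
    if A.size:
        r = float(np.max(np.abs(np.linalg.eigvals(A))))
        if r >= 0.8:
            scale = 0.75 / r
            g.edges = {k: w * scale for k, w in g.edges.items()}
    return g


class TestGraphMatrix:
    def test_edgeless_graph_is_zero(self):
        g = LabeledGraph(labels=[frozenset("a"), frozenset("b")])
        assert graph_matrix(g).entries == {}

    def test_single_edge_single_walk(self):
        g = LabeledGraph(
            labels=[frozenset("a"), frozenset("b")], edges={(0, 1): 0.9}
        )
        gm = graph_matrix(g)
        assert gm.entries == {("a", "b"): pytest.approx(0.9)}

    def test_acyclic_fixture_matches_walk_enumeration(self):
        # diamond: 0->1->3, 0->2->3 with distinct labels
        g = LabeledGraph(
            labels=[frozenset("s"), frozenset("p"), frozenset("q"),
                    frozenset("t")],
            edges={(0, 1): 0.9, (0, 2): 0.3, (1, 3): 0.9, (2, 3): 0.3},
        )
        got = graph_matrix(g).entries
        want = walk_sum_oracle(g, max_len=25)
        assert set(got) == set(want)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)
        # two paths s->t: 0.9*0.9 + 0.3*0.3
        assert got[("s", "t")] == pytest.approx(0.90, abs=1e-12)

    def test_oracle_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            g = random_graph(rng)
            got = graph_matrix(g).entries
            want = walk_sum_oracle(g)
            keys = set(got) | set(want)
            for k in keys:
                assert got.get(k, 0.0) == pytest.approx(
                    want.get(k, 0.0), abs=1e-9
                )

    def test_divergent_graph_is_hard_error(self):
        g = LabeledGraph(
            labels=[frozenset("a"), frozenset("b")],
            edges={(0, 1): 0.9, (1, 0): 2.0},
            graph_id="bad",
        )
        with pytest.raises(GraphKernelError, match="bad"):
            graph_matrix(g)

    def test_vertex_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, max_vertices=5)
        perm = [int(p) for p in rng.permutation(g.n_vertices)]  # old -> new
        labels = [None] * g.n_vertices
        for old, new in enumerate(perm):
            labels[new] = g.labels[old]
        g2 = LabeledGraph(
            labels=labels,
            edges={(perm[i], perm[j]): w for (i, j), w in g.edges.items()},
        )
        a, b = graph_matrix(g).entries, graph_matrix(g2).entries
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-10)

    def test_adding_edge_never_decreases_entries(self):
        g = LabeledGraph(
            labels=[frozenset("a"), frozenset("b"), frozenset("c")],
            edges={(0, 1): 0.3},
        )
        base = graph_matrix(g).entries
        g.edges[(1, 2)] = 0.3
        more = graph_matrix(g).entries
        for k, v in base.items():
            assert more.get(k, 0.0) >= v - 1e-12


class TestKernelValue:
    def test_zero_against_anything(self):
        g = LabeledGraph(labels=[frozenset("a"), frozenset("b")],
                         edges={(0, 1): 0.9})
        gm = graph_matrix(g)
        zero = graph_matrix(LabeledGraph(labels=[frozenset("a")]))
        assert kernel_value(gm, zero) == 0.0
        assert kernel_value(gm, zero, normalize=False) == 0.0

    def test_self_similarity_is_one(self):
        g = LabeledGraph(
            labels=[frozenset("ab"), frozenset("c")],
            edges={(0, 1): 0.5},
        )
        gm = graph_matrix(g)
        assert kernel_value(gm, gm) == pytest.approx(1.0)

    def test_hand_computed_product(self):
        from lbdkit.graph import GraphMatrix
        g1 = GraphMatrix({("a", "b"): 2.0, ("a", "c"): 1.0, ("b", "c"): 3.0})
        g2 = GraphMatrix({("a", "b"): 0.5, ("b", "c"): 2.0, ("c", "c"): 7.0})
        # shared keys: (a,b) and (b,c) -> 2*0.5 + 3*2 = 7
        assert kernel_value(g1, g2, normalize=False) == pytest.approx(7.0)


class TestGram:
    def test_single_graph_normalized(self, two_token_sentence):
        g = build_graph(two_token_sentence)
        K = gram_matrix([g])
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(1.0)

    def test_symmetric_psd_on_synthetic_graphs(self):
        from lbdkit.synth import GeneratorConfig, generate_corpus
        sents, _ = generate_corpus(GeneratorConfig(n_sentences=10, seed=5))
        graphs = [build_graph(s) for s in sents]
        K = gram_matrix(graphs)
        assert np.array_equal(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert np.allclose(np.diag(K), 1.0)

    def test_cross_gram_consistent_with_gram(self):
        from lbdkit.synth import GeneratorConfig, generate_corpus
        sents, _ = generate_corpus(GeneratorConfig(n_sentences=6, seed=9))
        graphs = [build_graph(s) for s in sents]
        mats = [graph_matrix(g) for g in graphs]
        K = gram_matrix(graphs)
        C = cross_gram(mats, mats)
        assert np.allclose(K, C, atol=1e-10)


class TestBuildGraph:
    def test_two_token_pair_all_on_shortest_path(self, two_token_sentence):
        g = build_graph(two_token_sentence)
        # PSS: 2 word + 1 link vertices, LOS: 2 word vertices
        assert g.n_vertices == 5
        assert g.shortest_path_vertices == frozenset({0, 1, 2})
        pss_edges = {k: w for k, w in g.edges.items() if max(k) <= 2}
        assert set(pss_edges.values()) == {0.9}
        los_edges = {k: w for k, w in g.edges.items() if min(k) >= 3}
        assert set(los_edges.values()) == {0.3}

    def test_ip_specialization_and_entity_anonymization(
        self, two_token_sentence
    ):
        g = build_graph(two_token_sentence)
        assert g.labels[0] == frozenset({"ENTITY1_IP", "NN_IP"})
        assert g.labels[1] == frozenset({"ENTITY2_IP", "NN_IP"})
        assert g.labels[2] == frozenset({"nsubj_IP"})

    def test_los_positional_tags(self):
        sent = make_sentence(
            [("before", "RB"), ("C1", "NN"), ("mid", "NN"), ("C2", "NN"),
             ("after", "RB")],
            mentions=[("m1", 1, 2, "C1", "Finding"),
                      ("m2", 3, 4, "C2", "Finding")],
        )
        g = build_graph(sent)
        los = g.labels[-5:]
        assert los[0] == frozenset({"before_B", "RB_B"})
        assert los[1] == frozenset({"ENTITY1_M", "NN_M"})
        assert los[2] == frozenset({"mid_M", "NN_M"})
        assert los[4] == frozenset({"after_A", "RB_A"})
        # tokens outside the pair are never tagged _M
        for labs in (los[0], los[4]):
            assert not any(l.endswith("_M") for l in labs)

    def test_nine_token_fixture_counts(self):
        """Clause with a third (non-candidate) entity: hand-enumerated."""
        sent = make_sentence(
            [("the", "DT"), ("C1", "NN"), ("raises", "VBZ"), ("C2", "NN"),
             ("and", "CC"), ("C3", "NN"), ("in", "IN"), ("serum", "NN"),
             (".", "PUNCT")],
            mentions=[("m1", 1, 2, "CA", "Finding"),
                      ("m2", 3, 4, "CB", "Finding"),
                      ("m3", 5, 6, "CC", "Finding")],
            edges=[(2, 1, "nsubj"), (2, 3, "dobj"), (3, 5, "conj"),
                   (0, 2, "dep"), (2, 6, "prep"), (6, 7, "pobj"),
                   (7, 8, "punct")],
        )
        g = build_graph(sent)
        # 9 PSS word + 7 link + 9 LOS word vertices
        assert g.n_vertices == 25
        # PSS edges: 2 per dependency; LOS chain: 8
        assert len(g.edges) == 2 * 7 + 8
        # shortest path: C1 -> nsubj -> raises -> dobj -> C2
        link_nsubj = 9  # first link vertex
        link_dobj = 10
        assert g.shortest_path_vertices == frozenset(
            {1, link_nsubj, 2, link_dobj, 3}
        )
        assert g.labels[5] == frozenset({"ENTITY", "NN"})
        n_shortest = sum(1 for w in g.edges.values() if w == 0.9)
        assert n_shortest == 4

    def test_disconnected_pair_warns_and_keeps_heads(self):
        sent = make_sentence(
            [("C1", "NN"), ("x", "NN"), ("C2", "NN")],
            mentions=[("m1", 0, 1, "C1", "Finding"),
                      ("m2", 2, 3, "C2", "Finding")],
            edges=[(0, 1, "dep")],  # C2 unreachable
        )
        with pytest.warns(UserWarning, match="no dependency path"):
            g = build_graph(sent)
        assert g.shortest_path_vertices == frozenset({0, 2})

    def test_symmetrized_edges_doubles_edge_count(self, two_token_sentence):
        g0 = build_graph(two_token_sentence, KernelConfig())
        g1 = build_graph(two_token_sentence,
                         KernelConfig(symmetrize_edges=True))
        assert len(g1.edges) == 2 * len(g0.edges)

    def test_bad_weight_config_rejected(self):
        with pytest.raises(GraphKernelError):
            KernelConfig(w_shortest=1.0)
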