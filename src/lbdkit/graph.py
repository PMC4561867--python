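"""All-paths dependency graph kernel.

Each candidate-pair sentence becomes one labeled directed graph that is
the disjoint union of two subgraphs:

* the parse structure subgraph (PSS): one word vertex per token (labels:
  lemma and POS) and one link vertex per dependency edge (label: the
  dependency relation), wired governor → link → dependent.  Every vertex
  on the shortest undirected dependency path between the two candidate
  entity heads has its labels specialized with an ``_IP`` suffix, and the
  edges along that path carry weight 0.9; all other edges carry 0.3.
* the linear order subgraph (LOS): one word vertex per token, chained
  left to right at weight 0.3, with every label carrying a positional
  tag — ``_B`` before the first entity, ``_M`` from the first entity
  through the second, ``_A`` after it.

Candidate entities are anonymized to ``ENTITY1`` / ``ENTITY2`` (other
known entities to ``ENTITY``) so the kernel generalizes across concepts.
Summing the weights of all walks between every ordered vertex pair via
the Neumann series ``Σ_{n≥1} A^n = (I−A)^{-1} − I`` gives a label-pair
matrix G = Lᵀ((I−A)⁻¹−I)L; the kernel between two sentences is the inner
product of their G matrices over shared label pairs, optionally
normalized to self-similarity 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import sparse

from lbdkit.corpus import AnnotatedSentence

__all__ = [
    "KernelConfig",
    "LabeledGraph",
    "GraphMatrix",
    "GraphKernelError",
    "build_graph",
    "graph_matrix",
    "kernel_value",
    "gram_matrix",
    "cross_gram",
    "stack_graph_matrices",
]

ENTITY1 = "ENTITY1"
ENTITY2 = "ENTITY2"
ENTITY = "ENTITY"
IP_SUFFIX = "_IP"


class GraphKernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelConfig:
    """Weights and switches for graph construction and kernel values.

    ``w_shortest``/``w_other`` are the edge weights on and off the
    shortest dependency path; both must lie in (0, 1) so the walk series
    converges on any graph whose edge structure is acyclic (trees and
    chains, as produced here).  ``ip_additive`` keeps the plain label
    alongside the ``_IP``-specialized one instead of replacing it.
    """

    w_shortest: float = 0.9
    w_other: float = 0.3
    symmetrize_edges: bool = False
    normalize: bool = True
    ip_additive: bool = False

    def __post_init__(self) -> None:
        for w in (self.w_shortest, self.w_other):
            if not (0.0 < w < 1.0):
                raise GraphKernelError(f"edge weights must be in (0,1), got {w}")


@dataclass
class LabeledGraph:
    """Vertices with label sets plus a sparse weighted edge map."""

    labels: list[frozenset[str]]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)
    shortest_path_vertices: frozenset[int] = frozenset()
    graph_id: str = ""

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    def edge_matrix(self) -> np.ndarray:
        A = np.zeros((self.n_vertices, self.n_vertices))
        for (i, j), w in self.edges.items():
            A[i, j] = w
        return A


@dataclass
class GraphMatrix:
    """The label-pair walk-weight matrix G, stored sparsely by label names."""

    entries: dict[tuple[str, str], float]
    graph_id: str = ""

    def self_kernel(self) -> float:
        return float(sum(v * v for v in self.entries.values()))


# ---------------------------------------------------------------------------
# Graph construction


def _positional_tag(idx: int, e1_start: int, e2_end: int) -> str:
    if idx < e1_start:
        return "_B"
    if idx >= e2_end:
        return "_A"
    return "_M"


def build_graph(sent: AnnotatedSentence, cfg: KernelConfig | None = None) -> LabeledGraph:
    """Build the PSS+LOS graph for a sentence's candidate pair."""
    cfg = cfg or KernelConfig()
    e1, e2 = sent.e1, sent.e2
    n = len(sent.tokens)

    # entity anonymization shared by both subgraphs
    lexical: dict[int, str] = {}
    for t in sent.tokens:
        lexical[t.index] = t.lemma.lower()
    for m in sent.mentions:
        tag = ENTITY
        if m.mention_id == e1.mention_id:
            tag = ENTITY1
        elif m.mention_id == e2.mention_id:
            tag = ENTITY2
        for i in range(m.start, m.end):
            lexical[i] = tag

    labels: list[frozenset[str]] = []
    edges: dict[tuple[int, int], float] = {}

    # --- PSS: word vertices 0..n-1, link vertices n..n+|edges|-1
    for t in sent.tokens:
        labels.append(frozenset({lexical[t.index], t.pos}))
    link_base = n
    for k, e in enumerate(sent.edges):
        labels.append(frozenset({e.relation}))
        edges[(e.governor, link_base + k)] = cfg.w_other
        edges[(link_base + k, e.dependent)] = cfg.w_other

    # shortest undirected path between the entity heads, through link vertices
    ug = nx.Graph()
    ug.add_nodes_from(range(link_base + len(sent.edges)))
    for k, e in enumerate(sent.edges):
        ug.add_edge(e.governor, link_base + k)
        ug.add_edge(link_base + k, e.dependent)
    src, dst = e1.head, e2.head
    try:
        paths = nx.all_shortest_paths(ug, src, dst)
        path = min(paths)  # lexicographically smallest index sequence
        on_path = frozenset(path)
        path_edges = set(zip(path, path[1:]))
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        warnings.warn(
            f"sentence {sent.sentence_id!r}: no dependency path between "
            "candidate heads; shortest-path set reduced to the heads"
        )
        on_path = frozenset({src, dst})
        path_edges = set()

    for v in on_path:
        specialized = frozenset(lab + IP_SUFFIX for lab in labels[v])
        labels[v] = labels[v] | specialized if cfg.ip_additive else specialized
    for (i, j) in list(edges):
        if (i, j) in path_edges or (j, i) in path_edges:
            edges[(i, j)] = cfg.w_shortest

    # --- LOS: word vertices appended after PSS, chained left-to-right
    los_base = link_base + len(sent.edges)
    for t in sent.tokens:
        tag = _positional_tag(t.index, e1.start, e2.end)
        labels.append(frozenset({lexical[t.index] + tag, t.pos + tag}))
    for i in range(n - 1):
        edges[(los_base + i, los_base + i + 1)] = cfg.w_other

    if cfg.symmetrize_edges:
        for (i, j), w in list(edges.items()):
            edges.setdefault((j, i), w)

    return LabeledGraph(
        labels=labels,
        edges=edges,
        shortest_path_vertices=on_path,
        graph_id=sent.sentence_id,
    )


# ---------------------------------------------------------------------------
# Graph matrix and kernel values


def graph_matrix(g: LabeledGraph) -> GraphMatrix:
    """Closed-form sum of all walk weights between label occurrences.

    Computes W = (I−A)⁻¹ − I (the Neumann series of the edge matrix) and
    aggregates W over ordered label pairs: G[a, b] = Σ_{u has a, v has b}
    W[u, v].  A spectral radius ≥ 1 means the walk series diverges and is
    a hard error — rescaling weights silently would change the model.
    """
    A = g.edge_matrix()
    if A.size:
        radius = float(np.max(np.abs(np.linalg.eigvals(A))))
        if radius >= 1.0 - 1e-12:
            raise GraphKernelError(
                f"graph {g.graph_id!r}: spectral radius {radius:.6f} >= 1; "
                "the all-paths series does not converge"
            )
    n = g.n_vertices
    W = np.linalg.inv(np.eye(n) - A) - np.eye(n)

    entries: dict[tuple[str, str], float] = {}
    # drop numerical dust from the inversion; true walk weights are far larger
    nz_u, nz_v = np.nonzero(np.abs(W) > 1e-12)
    for u, v in zip(nz_u, nz_v):
        w = W[u, v]
        for a in g.labels[u]:
            for b in g.labels[v]:
                key = (a, b)
                entries[key] = entries.get(key, 0.0) + w
    return GraphMatrix(entries=entries, graph_id=g.graph_id)


def kernel_value(
    G1: GraphMatrix, G2: GraphMatrix, normalize: bool = True
) -> float:
    """k(G, G′) = Σ over shared label pairs of G·G′; optionally normalized.

    Under normalization the value is k/√(k₁₁·k₂₂), defined as 0 when
    either self-kernel vanishes.
    """
    small, large = G1.entries, G2.entries
    if len(small) > len(large):
        small, large = large, small
    k = 0.0
    for key, v in small.items():
        w = large.get(key)
        if w is not None:
            k += v * w
    if not normalize:
        return k
    k11, k22 = G1.self_kernel(), G2.self_kernel()
    if k11 <= 0.0 or k22 <= 0.0:
        return 0.0
    return k / np.sqrt(k11 * k22)


def stack_graph_matrices(
    mats: Sequence[GraphMatrix],
    registry: dict[tuple[str, str], int] | None = None,
) -> tuple[sparse.csr_matrix, dict[tuple[str, str], int]]:
    """Represent graph matrices as rows of a sparse label-pair space.

    The registry maps label pairs to columns and is append-only, so rows
    produced under a grown registry remain comparable: the kernel between
    two graphs is exactly the dot product of their rows.
    """
    registry = {} if registry is None else registry
    rows, cols, vals = [], [], []
    for r, gm in enumerate(mats):
        for key, v in gm.entries.items():
            j = registry.get(key)
            if j is None:
                j = len(registry)
                registry[key] = j
            rows.append(r)
            cols.append(j)
            vals.append(v)
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(mats), max(len(registry), 1))
    )
    return X, registry


def _normalized_rows(X: sparse.csr_matrix) -> sparse.csr_matrix:
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    return sparse.diags(inv) @ X


def gram_matrix(
    graphs: Sequence[LabeledGraph], cfg: KernelConfig | None = None
) -> np.ndarray:
    """Pairwise kernel matrix for a list of graphs (symmetric, PSD)."""
    cfg = cfg or KernelConfig()
    if not graphs:
        raise GraphKernelError("gram_matrix requires at least one graph")
    mats = []
    for i, g in enumerate(graphs):
        try:
            mats.append(graph_matrix(g))
        except GraphKernelError as exc:
            raise GraphKernelError(f"graph #{i}: {exc}") from exc
    X, _ = stack_graph_matrices(mats)
    if cfg.normalize:
        X = _normalized_rows(X)
    K = (X @ X.T).toarray()
    return (K + K.T) / 2.0


def cross_gram(
    mats_a: Sequence[GraphMatrix],
    mats_b: Sequence[GraphMatrix],
    normalize: bool = True,
) -> np.ndarray:
    """Kernel matrix between two collections of precomputed G matrices."""
    registry: dict[tuple[str, str], int] = {}
    Xb, registry = stack_graph_matrices(mats_b, registry)
    Xa, registry = stack_graph_matrices(mats_a, registry)
    width = max(len(registry), 1)
    Xa.resize((Xa.shape[0], width))
    Xb.resize((Xb.shape[0], width))
    if normalize:
        Xa = _normalized_rows(Xa)
        Xb = _normalized_rows(Xb)
    return (Xa @ Xb.T).toarray()
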