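"""Arbor detection by normalized graph-cut on the reconstruction tree.

A neuron is viewed as a graph whose vertices are reconstruction nodes and
whose edges are the parent-child pairs, weighted by the similarity
s = exp(-d/σ) where d is the 3D Euclidean parent-child distance (native
units, σ = 1 by default).  Removing k-1 tree edges splits the neuron into
k connected "arbors"; the cut is chosen to minimize the normalized score

    total cross-cluster similarity / total within-cluster similarity.

Because arbors are separated by long, low-similarity bridge paths, the
optimal cut at each k severs the lightest bridges.  The number of arbors
is chosen across k = 2..8 by mean silhouette of the node coordinates
under each candidate partition (see detect_arbors), with a single-arbor
fallback when no partition is spatially coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .swc import NeuronMorphology, TYPE_AXON, TYPE_SOMA


@dataclass
class SimilarityGraph:
    """Tree-structured similarity graph: one edge per parent-child pair."""

    n: int
    edges: np.ndarray  # (m, 2) int vertex indices
    weights: np.ndarray  # (m,) similarities in (0, 1]
    coords: np.ndarray | None = None
    node_ids: np.ndarray | None = None  # original SWC ids per vertex

    @property
    def m(self) -> int:
        return len(self.edges)


def build_graph(
    neuron: NeuronMorphology, sigma: float = 1.0, rows=None
) -> SimilarityGraph:
    """Similarity graph with weight exp(-d/σ) per parent-child edge.

    ``rows`` optionally restricts the graph to a subset of node rows (the
    induced edges are kept); vertex indices then refer to that subset.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xyz = neuron.coords()
    edges = neuron.edges()
    ids = neuron.nodes["id"].to_numpy()
    if rows is not None:
        rows = np.asarray(sorted(rows), dtype=np.int64)
        pos = -np.ones(len(neuron), dtype=np.int64)
        pos[rows] = np.arange(len(rows))
        keep = (pos[edges[:, 0]] >= 0) & (pos[edges[:, 1]] >= 0)
        edges = np.column_stack([pos[edges[keep, 0]], pos[edges[keep, 1]]])
        xyz = xyz[rows]
        ids = ids[rows]
    d = np.linalg.norm(xyz[edges[:, 0]] - xyz[edges[:, 1]], axis=1)
    return SimilarityGraph(
        n=len(xyz),
        edges=edges,
        weights=np.exp(-d / sigma),
        coords=xyz,
        node_ids=ids,
    )


def component_labels(graph: SimilarityGraph, cut_edges) -> np.ndarray:
    """Connected-component labels after removing the given edge indices."""
    keep = np.ones(graph.m, dtype=bool)
    keep[list(cut_edges)] = False
    e = graph.edges[keep]
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(graph.n, graph.n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def normalized_score(graph: SimilarityGraph, labels: np.ndarray) -> float:
    """Total cross-cluster similarity divided by total within-cluster similarity."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("partition must have at least 2 non-empty parts")
    cross = labels[graph.edges[:, 0]] != labels[graph.edges[:, 1]]
    within = float(graph.weights[~cross].sum())
    if within == 0:
        raise ValueError("degenerate partition: within-cluster similarity is 0")
    return float(graph.weights[cross].sum()) / within


def _score_of_cut(graph: SimilarityGraph, cut, total: float) -> float:
    c = float(graph.weights[list(cut)].sum())
    within = total - c
    if within <= 0:
        return np.inf
    return c / within


def _cut_feasible(graph: SimilarityGraph, cut, min_part_size: int) -> bool:
    if min_part_size <= 1:
        return True
    labels = component_labels(graph, cut)
    _, counts = np.unique(labels, return_counts=True)
    return bool(counts.min() >= min_part_size)


def partition_k(
    graph: SimilarityGraph,
    k: int,
    restrict_connected: bool = True,
    min_part_size: int = 1,
    exact_limit: int = 200_000,
    seed: int = 0,
) -> np.ndarray:
    """Partition the tree into k parts minimizing the normalized score.

    With ``restrict_connected`` (default) the parts are the connected
    components left by removing k-1 tree edges: the cut set is found by
    exhaustive enumeration when the number of candidate combinations is
    small enough, otherwise by greedy edge removal followed by local
    swap refinement.  Without the restriction, a spectral relaxation on
    the normalized Laplacian is used and parts need not be connected.
    Ties break toward the lexicographically smallest cut-edge set.
    """
    if not 2 <= k <= graph.n:
        raise ValueError(f"k={k} out of range 2..{graph.n}")
    if not restrict_connected:
        return _spectral_partition(graph, k, seed)
    if graph.m < k - 1:
        raise ValueError(f"cannot split {graph.m + 1}-part forest into {k} parts")
    total = float(graph.weights.sum())

    if comb(graph.m, k - 1) <= exact_limit:
        best, best_score = None, np.inf
        for cut in combinations(range(graph.m), k - 1):
            score = _score_of_cut(graph, cut, total)
            if score < best_score and _cut_feasible(graph, cut, min_part_size):
                labels = component_labels(graph, cut)
                if len(np.unique(labels)) == k:
                    best, best_score = cut, score
        if best is None:
            raise ValueError(f"no feasible partition into {k} parts")
        return component_labels(graph, best)

    # Greedy: remove one edge at a time, each time the edge that minimizes
    # the resulting score subject to the feasibility constraints.
    cut: list = []
    for _ in range(k - 1):
        best_e, best_score = None, np.inf
        for e in range(graph.m):
            if e in cut:
                continue
            trial = cut + [e]
            score = _score_of_cut(graph, trial, total)
            if score < best_score and _cut_feasible(graph, trial, min_part_size):
                labels = component_labels(graph, trial)
                if len(np.unique(labels)) == len(trial) + 1:
                    best_e, best_score = e, score
        if best_e is None:
            raise ValueError(f"no feasible partition into {k} parts")
        cut.append(best_e)

    # Local refinement: try swapping each cut edge for each kept edge.
    improved = True
    while improved:
        improved = False
        current = _score_of_cut(graph, cut, total)
        for i in range(len(cut)):
            for e in range(graph.m):
                if e in cut:
                    continue
                trial = cut[:i] + [e] + cut[i + 1:]
                score = _score_of_cut(graph, trial, total)
                if score < current - 1e-15 and _cut_feasible(
                    graph, trial, min_part_size
                ):
                    labels = component_labels(graph, trial)
                    if len(np.unique(labels)) == k:
                        cut, current, improved = trial, score, True
    return component_labels(graph, sorted(cut))


def _spectral_partition(graph: SimilarityGraph, k: int, seed: int) -> np.ndarray:
    """Spectral relaxation on the normalized Laplacian of the edge weights."""
    from scipy.linalg import eigh
    from sklearn.cluster import KMeans

    w = np.zeros((graph.n, graph.n))
    w[graph.edges[:, 0], graph.edges[:, 1]] = graph.weights
    w[graph.edges[:, 1], graph.edges[:, 0]] = graph.weights
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv = 1.0 / np.sqrt(deg)
    lap = np.eye(graph.n) - d_inv[:, None] * w * d_inv[None, :]
    _, vecs = eigh(lap, subset_by_index=[0, k - 1])
    emb = vecs / np.maximum(np.linalg.norm(vecs, axis=1, keepdims=True), 1e-12)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(emb)


# -- arbor sets ----------------------------------------------------------


@dataclass
class Arbor:
    index: int
    node_ids: np.ndarray
    contains_soma: bool
    centre_node_id: int
    cable_length: float


@dataclass
class ArborSet:
    """Partition of a neuron into spatially coherent arbors."""

    labels: dict  # SWC node id -> arbor index
    arbors: list = field(default_factory=list)
    k: int = 1
    selection_scores: dict = field(default_factory=dict)
    normalized_scores: dict = field(default_factory=dict)

    @property
    def soma_arbor(self) -> Arbor:
        for arbor in self.arbors:
            if arbor.contains_soma:
                return arbor
        raise ValueError("no soma arbor flagged")

    def non_soma_arbors(self) -> list:
        return [a for a in self.arbors if not a.contains_soma]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.labels.items()), columns=["node_id", "arbor_id"]
        )


def _centre_node(xyz: np.ndarray) -> int:
    """Index of the node with the shortest average distance to the others."""
    if len(xyz) == 1:
        return 0
    d = cdist(xyz, xyz)
    return int(np.argmin(d.mean(axis=1)))


def _axon_rows_with_path_to_root(neuron: NeuronMorphology) -> np.ndarray:
    """Axon rows plus every ancestor row, so the subset stays connected."""
    types = neuron.nodes["type"].to_numpy()
    par = neuron.parent_index()
    keep = set(np.flatnonzero(types == TYPE_AXON).tolist())
    for i in list(keep):
        j = par[i]
        while j >= 0 and j not in keep:
            keep.add(int(j))
            j = par[j]
    return np.array(sorted(keep), dtype=np.int64)


def detect_arbors(
    neuron: NeuronMorphology,
    k_range=range(2, 9),
    subtree: str = "axon",
    sigma: float = 1.0,
    min_arbor_size: int = 10,
    silhouette_floor: float = 0.4,
    exact_limit: int = 200_000,
) -> ArborSet:
    """Detect and partition a neuron's arbors.

    For each candidate arbor count k in ``k_range`` the tree is cut by
    :func:`partition_k` (connected parts, each at least ``min_arbor_size``
    nodes), and k* is the candidate whose partition has the highest mean
    silhouette of node coordinates.  If no candidate is feasible, or the
    best silhouette falls below ``silhouette_floor``, the neuron is a
    single arbor.  The arbor containing the soma (root) is the soma arbor.
    """
    if subtree == "axon":
        rows = _axon_rows_with_path_to_root(neuron)
        if len(rows) == 0:
            rows = np.arange(len(neuron))
    elif subtree == "all":
        rows = np.arange(len(neuron))
    else:
        raise ValueError("subtree must be 'axon' or 'all'")
    graph = build_graph(neuron, sigma=sigma, rows=rows)
    xyz = graph.coords
    soma_row = neuron.soma_index()
    soma_vertex = int(np.searchsorted(rows, soma_row)) if soma_row in rows else 0

    candidates: dict = {}
    sil: dict = {}
    nscores: dict = {}
    if graph.n >= 2 * min_arbor_size:
        for k in k_range:
            if k < 2 or graph.m < k - 1 or graph.n < k * min_arbor_size:
                continue
            try:
                labels = partition_k(
                    graph, k, min_part_size=min_arbor_size, exact_limit=exact_limit
                )
            except ValueError:
                continue
            candidates[k] = labels
            sil[k] = float(silhouette_score(xyz, labels))
            nscores[k] = normalized_score(graph, labels)

    best_k = None
    if candidates:
        best = max(sil.values())
        if best >= silhouette_floor:
            best_k = min(k for k, s in sil.items() if s == best)

    if best_k is None:
        labels = np.zeros(graph.n, dtype=int)
        k = 1
    else:
        labels = candidates[best_k]
        k = best_k

    # Renumber so arbor 0 is the soma arbor, then by descending size.
    soma_label = labels[soma_vertex]
    order = [soma_label] + sorted(
        (l for l in np.unique(labels) if l != soma_label),
        key=lambda l: -int(np.sum(labels == l)),
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])

    edge_len = np.linalg.norm(
        xyz[graph.edges[:, 0]] - xyz[graph.edges[:, 1]], axis=1
    )
    arbors = []
    for a in range(k):
        members = np.flatnonzero(labels == a)
        within = (
            labels[graph.edges[:, 0]] == a
        ) & (labels[graph.edges[:, 1]] == a)
        arbors.append(
            Arbor(
                index=a,
                node_ids=graph.node_ids[members],
                contains_soma=bool(labels[soma_vertex] == a),
                centre_node_id=int(
                    graph.node_ids[members[_centre_node(xyz[members])]]
                ),
                cable_length=float(edge_len[within].sum()),
            )
        )
    return ArborSet(
        labels={int(graph.node_ids[i]): int(labels[i]) for i in range(graph.n)},
        arbors=arbors,
        k=k,
        selection_scores=sil,
        normalized_scores=nscores,
    )


def local_axon(neuron: NeuronMorphology, radius: float = 200.0) -> np.ndarray:
    """Rows of axon nodes within ``radius`` µm (Euclidean) of the soma."""
    soma = neuron.soma_position()
    types = neuron.nodes["type"].to_numpy()
    d = np.linalg.norm(neuron.coords() - soma, axis=1)
    return np.flatnonzero((types == TYPE_AXON) & (d <= radius))
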