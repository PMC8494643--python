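"""Projection-concordance and clustering statistics.

Four procedures live here:

* **neuron-beta** — regression-slope concordance of a single cell's
  projection vector S with its group's mean mesoscale vector M:
  Cov(M, S) / Var(M).
* **Projection-space clustering** (L5 ET style) — PCA retaining >90% of
  variance, 2D UMAP, then agglomerative clustering of the embedding cut
  at a configurable distance.
* **SNN consensus co-clustering** (Car3 style) — per feature set, a
  ranked k-nearest-neighbour graph scored by the shared-nearest-neighbour
  similarity, fast-greedy community detection on resampled subsets
  (default 1,000 iterations at 95% sampling), consensus matrices fused by
  a weighted average, agglomerative cut, and iterative Mann-Whitney
  outlier pruning.
* **k-means arbor typing** — z-scored arbor features, PCA to 95% of
  variance, UMAP, k-means with cluster ids ordered by mean arbor radius
  (type 1 = smaller).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import mannwhitneyu
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA

from .features import znormalize


# -- neuron-beta ---------------------------------------------------------


def neuron_beta(M, S) -> float:
    """Cov(M, S) / Var(M): the slope of the single cell on its group mean.

    Equals the ordinary least-squares slope of S regressed on M; 1 when
    S = M, a when S = a*M + b.
    """
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if M.shape != S.shape or M.ndim != 1:
        raise ValueError("M and S must be 1D vectors of equal length")
    var = np.var(M, ddof=1)
    if var == 0:
        raise ValueError("Var(M) = 0: mesoscale mean vector is constant")
    cov = np.cov(M, S, ddof=1)[0, 1]
    return float(cov / var)


# -- dimensionality reduction -------------------------------------------


def pca_reduce(X, var_fraction: float = 0.9) -> np.ndarray:
    """Scores on the smallest leading-PC set explaining > var_fraction."""
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    pca = PCA()
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pc = int(np.searchsorted(cum, var_fraction) + 1)
    n_pc = min(n_pc, scores.shape[1])
    return scores[:, :n_pc]


def embed_2d(X, n_neighbors: int = 15, seed: int = 0) -> np.ndarray:
    """Deterministic 2D UMAP embedding (given the seed)."""
    X = np.asarray(X, dtype=float)
    if len(X) <= n_neighbors:
        raise ValueError(
            f"n={len(X)} too small for n_neighbors={n_neighbors}"
        )
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, random_state=seed
        )
        return reducer.fit_transform(X)


def cluster_projection_et(
    strengths,
    seed: int = 0,
    distance_threshold: float | None = 10.0,
    n_clusters: int | None = None,
    var_fraction: float = 0.9,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Projection-space clustering of cells from their strength vectors.

    Pipeline: PCA keeping >``var_fraction`` of variance, 2D UMAP, then
    agglomerative (Ward) clustering of the embedding cut either at
    ``distance_threshold`` (the dendrogram branch length, a configuration
    value standing in for a manual cut) or into ``n_clusters``.
    """
    X = np.asarray(strengths, dtype=float)
    if np.allclose(X, X[0]):
        return np.zeros(len(X), dtype=int)  # identical cells: one cluster
    emb = embed_2d(pca_reduce(X, var_fraction), n_neighbors=n_neighbors, seed=seed)
    if n_clusters is not None:
        agg = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    else:
        agg = AgglomerativeClustering(
            n_clusters=None, distance_threshold=distance_threshold, linkage="ward"
        )
    return agg.fit_predict(emb)


# -- shared-nearest-neighbour similarity ---------------------------------


def ranked_knn(X, k: int) -> np.ndarray:
    """(n, k) neighbour indices ordered by rank (1 = closest), self excluded."""
    X = np.asarray(X, dtype=float)
    d = squareform(pdist(X))
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def snn_similarity(neigh_i, neigh_j, k: int, as_printed: bool = False) -> float:
    """Shared-nearest-neighbour similarity of two ranked neighbour lists.

    S = max over common neighbours v of k - (rank_i(v) + rank_j(v)) / 2,
    with ranks 1-based; 0 when the lists share no neighbour.  The
    ``as_printed`` variant halves rank_j once more
    (k - 1/2 [rank_i + 1/2 rank_j]), an asymmetric alternative form.
    """
    ranks_i = {int(v): r + 1 for r, v in enumerate(neigh_i)}
    ranks_j = {int(v): r + 1 for r, v in enumerate(neigh_j)}
    common = ranks_i.keys() & ranks_j.keys()
    if not common:
        return 0.0
    if as_printed:
        return float(
            max(k - 0.5 * (ranks_i[v] + 0.5 * ranks_j[v]) for v in common)
        )
    return float(max(k - 0.5 * (ranks_i[v] + ranks_j[v]) for v in common))


def snn_matrix(X, k: int) -> np.ndarray:
    """Pairwise SNN similarity matrix (symmetric form, vectorized).

    Uses the min-plus identity: with P[i, v] = rank of v in i's list
    (inf if absent), S(i, j) = max(0, k - min_v (P[i,v] + P[j,v]) / 2).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    nn = ranked_knn(X, k)
    P = np.full((n, n), np.inf)
    rows = np.repeat(np.arange(n), k)
    P[rows, nn.ravel()] = np.tile(np.arange(1, k + 1), n)
    best = np.full((n, n), np.inf)
    for v in range(n):
        col = P[:, v]
        np.minimum(best, col[:, None] + col[None, :], out=best)
    S = k - best / 2.0
    S[~np.isfinite(best)] = 0.0
    S = np.maximum(S, 0.0)
    np.fill_diagonal(S, 0.0)
    return S


# -- consensus co-clustering ---------------------------------------------


@dataclass
class CoclusterResult:
    """Consensus co-clustering output.

    ``consensus`` is the fused n x n matrix of co-clustering rates in
    [0, 1] (diagonal 1); ``per_set`` holds one such matrix per feature
    set; ``labels`` are the final cluster ids (-1 = unassigned /
    sub-minimum cluster), ``outliers`` the pruned sample positions.
    """

    consensus: np.ndarray
    per_set: list = field(default_factory=list)
    weights: np.ndarray | None = None
    labels: np.ndarray | None = None
    outliers: list = field(default_factory=list)
    iterations: int = 0
    log: list = field(default_factory=list)


def _snn_communities(X, k_nn: int, seed: int) -> np.ndarray:
    S = snn_matrix(X, k_nn)
    src, dst = np.nonzero(np.triu(S, 1))
    g = igraph.Graph(
        n=len(X), edges=list(zip(src.tolist(), dst.tolist())), directed=False
    )
    if g.ecount() == 0:
        return np.arange(len(X))
    weights = S[src, dst].tolist()
    dendro = g.community_fastgreedy(weights=weights)
    return np.asarray(dendro.as_clustering().membership)


def cocluster(
    feature_sets,
    k_nn: int = 10,
    iters: int = 1000,
    sample_frac: float = 0.95,
    weights=None,
    seed: int = 0,
) -> CoclusterResult:
    """Consensus co-clustering over resampled SNN community detection.

    For each feature set (rows = shared entities, already z-scored /
    strength-transformed by the caller), ``iters`` iterations each draw
    ``sample_frac`` of the samples, build the SNN graph and run
    fast-greedy community detection; the co-clustering score of a pair is
    the number of times it is co-clustered divided by the number of times
    it is co-sampled.  The overall consensus is the weighted average of
    the per-set matrices (equal weights by default).
    """
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must be in (0, 1]")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    mats = [np.asarray(f, dtype=float) for f in feature_sets]
    n = len(mats[0])
    if any(len(m) != n for m in mats):
        raise ValueError("feature sets must share their rows")
    weights = (
        np.full(len(mats), 1.0 / len(mats))
        if weights is None
        else np.asarray(weights, dtype=float) / np.sum(weights)
    )
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(sample_frac * n)))

    per_set = []
    for X in mats:
        co = np.zeros((n, n))
        seen = np.zeros((n, n))
        for _ in range(iters):
            sub = np.sort(rng.choice(n, size=n_sub, replace=False))
            membership = _snn_communities(X[sub], min(k_nn, n_sub - 1), seed)
            seen[np.ix_(sub, sub)] += 1
            same = membership[:, None] == membership[None, :]
            co[np.ix_(sub, sub)] += same
        never = seen == 0
        if never.any() and n > 1:
            off_diag_never = never & ~np.eye(n, dtype=bool)
            if off_diag_never.any():
                warnings.warn(
                    "some pairs were never co-sampled; their score is 0"
                )
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(seen > 0, co / np.maximum(seen, 1), 0.0)
        np.fill_diagonal(rate, 1.0)
        per_set.append(rate)

    fused = np.tensordot(weights, np.stack(per_set), axes=1)
    fused = (fused + fused.T) / 2.0
    np.fill_diagonal(fused, 1.0)
    return CoclusterResult(consensus=fused, per_set=per_set, weights=weights)


def cut_and_prune(
    result: CoclusterResult,
    min_cluster_size: int = 3,
    alpha: float = 0.01,
    distance_threshold: float | None = 0.5,
    n_clusters: int | None = None,
) -> CoclusterResult:
    """Cut the consensus matrix and iteratively prune outliers.

    Average-linkage agglomerative clustering on 1 - consensus, cut at
    ``distance_threshold`` (or into ``n_clusters``); each sample's
    within-cluster distances are compared against the pooled
    within-cluster background by a one-sided Mann-Whitney test and
    significantly distant samples are removed; repeat to a fixed point.
    Clusters below ``min_cluster_size`` are reported as unassigned (-1).
    """
    n = len(result.consensus)
    dist_full = 1.0 - result.consensus
    active = np.arange(n)
    outliers: list = []
    labels_full = np.full(n, -1, dtype=int)
    iteration = 0
    while True:
        iteration += 1
        if len(active) < 2:
            raise ValueError("outlier pruning removed almost all samples")
        d = dist_full[np.ix_(active, active)]
        if n_clusters is not None:
            agg = AgglomerativeClustering(
                n_clusters=min(n_clusters, len(active)),
                metric="precomputed",
                linkage="average",
            )
        else:
            agg = AgglomerativeClustering(
                n_clusters=None,
                distance_threshold=distance_threshold,
                metric="precomputed",
                linkage="average",
            )
        labels = agg.fit_predict(d)

        pooled = []
        per_sample: dict = {}
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if len(members) < 2:
                continue
            sub = d[np.ix_(members, members)]
            for row, i in enumerate(members):
                vals = np.delete(sub[row], row)
                per_sample[i] = vals
                pooled.append(vals)
        if not pooled:
            break
        background = np.concatenate(pooled)
        new_out = []
        for i, vals in per_sample.items():
            if len(vals) == 0:
                continue
            if np.ptp(background) == 0 and np.ptp(vals) == 0:
                continue  # all distances tied: nothing can be an outlier
            stat = mannwhitneyu(vals, background, alternative="greater")
            if stat.pvalue < alpha:
                new_out.append(i)
        result.log.append(
            {"iteration": iteration, "n_active": len(active), "n_outliers": len(new_out)}
        )
        if not new_out:
            labels_full[:] = -1
            for c in np.unique(labels):
                members = active[labels == c]
                if len(members) >= min_cluster_size:
                    labels_full[members] = c
            break
        outliers.extend(active[new_out].tolist())
        keep = np.setdiff1d(np.arange(len(active)), new_out)
        active = active[keep]

    result.labels = labels_full
    result.outliers = sorted(outliers)
    result.iterations = iteration
    return result


def cluster_arbors_kmeans(
    features: pd.DataFrame, k: int = 2, seed: int = 0, n_neighbors: int = 15
) -> np.ndarray:
    """k-means typing of cortical arbors on UMAP of z-scored features.

    ``features`` must contain the arbor feature columns including
    ``radius``.  Returns 1-based labels ordered by mean arbor radius
    (type 1 = smaller-radius arbors).
    """
    feats = pd.DataFrame(features).astype(float)
    if k == 1:
        return np.ones(len(feats), dtype=int)
    Z = znormalize(feats).to_numpy()
    emb = embed_2d(pca_reduce(Z, 0.95), n_neighbors=n_neighbors, seed=seed)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(emb)
    means = [
        feats.loc[raw == c, "radius"].mean() if "radius" in feats else c
        for c in range(k)
    ]
    order = np.argsort(means)
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    return np.array([remap[int(c)] for c in raw])
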