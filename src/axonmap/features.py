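"""Morphometric feature extraction and normalization.

Global features follow the L-measure conventions: bounding-box extents
(overall width/height/depth along x/y/z), total cable length, the maximum
Euclidean and path distances from the soma, the number of branches
(maximal unbranched paths, i.e. compartments) and the maximum branch
order (bifurcation count from the root).  Arbor-level features add the
anchor-based 2D area, radius and depth statistics.  PCA alignment
rotates a point cloud so axes are ordered by decreasing span and places
the soma at the origin.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .swc import NeuronMorphology, _unbranched_paths

GLOBAL_FEATURES = [
    "overall_width",
    "overall_height",
    "overall_depth",
    "total_length",
    "max_euclidean_distance",
    "max_path_distance",
    "n_branches",
    "max_branch_order",
]

ARBOR_FEATURES = ["area_2d", "total_length", "radius", "depth_mean", "depth_std"]


def _subtree_rows(neuron: NeuronMorphology, types) -> np.ndarray:
    mask = np.isin(neuron.nodes["type"].to_numpy(), list(types))
    return np.flatnonzero(mask)


def global_features(neuron: NeuronMorphology, types=None) -> pd.Series:
    """L-measure style global features of a neuron or typed subtree.

    ``types`` restricts to node type codes (e.g. (2,) for axon); the soma
    is always used as the distance origin.  Extents come from the
    axis-aligned bounding box; distances are measured from the soma along
    straight chords (Euclidean) or along the tree (path).
    """
    if types is None:
        rows = np.arange(len(neuron))
    else:
        rows = _subtree_rows(neuron, types)
    if len(rows) == 0:
        raise ValueError("empty subtree")
    row_set = set(rows.tolist())
    xyz = neuron.coords()
    soma = neuron.soma_position()
    par = neuron.parent_index()
    seg = neuron.segment_lengths()

    sub = xyz[rows]
    extents = sub.max(axis=0) - sub.min(axis=0)

    in_sub = np.zeros(len(neuron), dtype=bool)
    in_sub[rows] = True
    seg_rows = rows[(par[rows] >= 0) & in_sub[np.clip(par[rows], 0, None)]]
    total_length = float(seg[seg_rows].sum()) if len(seg_rows) else 0.0

    euclid = float(np.linalg.norm(sub - soma, axis=1).max())

    # Path distance from the root, accumulated over in-subtree chords.
    kids = neuron.children_map()
    path = np.zeros(len(neuron))
    order = np.zeros(len(neuron), dtype=int)
    root = neuron.root_index()
    stack = [root]
    while stack:
        i = stack.pop()
        for c in kids[i]:
            path[c] = path[i] + seg[c]
            order[c] = order[i] + (1 if len(kids[i]) >= 2 else 0)
            stack.append(c)
    max_path = float(path[rows].max())

    # Branches: maximal unbranched paths whose nodes lie in the subtree.
    n_branches = 0
    for p in _unbranched_paths(neuron):
        if all(i in row_set for i in p[1:]):
            n_branches += 1
    max_order = int(order[rows].max())

    return pd.Series(
        [
            float(extents[0]),
            float(extents[1]),
            float(extents[2]),
            total_length,
            euclid,
            max(max_path, euclid) if len(seg_rows) else euclid,
            n_branches,
            max_order,
        ],
        index=GLOBAL_FEATURES,
    )


def pca_align(points: np.ndarray, soma: np.ndarray) -> np.ndarray:
    """Rotate points so axes are ordered largest-to-smallest span, then
    shift so the soma lands at the origin.

    The rotation is the PCA basis of the point cloud (about its mean);
    each axis's sign is fixed by making its largest-|loading| coordinate
    positive, so the result is deterministic.  Rigid up to reflection:
    all pairwise distances are preserved.
    """
    points = np.asarray(points, dtype=float)
    soma = np.asarray(soma, dtype=float)
    centered = points - points.mean(axis=0)
    cov = np.cov(centered.T) if len(points) > 1 else np.eye(3)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    basis = evecs[:, order]
    for j in range(basis.shape[1]):
        i_max = int(np.argmax(np.abs(basis[:, j])))
        if basis[i_max, j] < 0:
            basis[:, j] = -basis[:, j]
    aligned = points @ basis
    return aligned - soma @ basis


def znormalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Feature-wise z-score: column mean 0, sample (n-1) sd 1.

    Constant columns become all-zero with a warning.
    """
    matrix = pd.DataFrame(matrix).astype(float)
    if len(matrix) < 2:
        raise ValueError("z-normalization needs at least 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant feature columns set to zero: {list(matrix.columns[constant])}"
        )
    sd = sd.replace(0.0, 1.0)
    out = (matrix - mean) / sd
    out.loc[:, constant] = 0.0
    return out
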