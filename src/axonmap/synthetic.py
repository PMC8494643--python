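"""Synthetic fixtures: toy atlas, planted-arbor neurons, planted
projection populations, mesoscale tables and topographic populations.

Every generator is deterministic given its seed and emits the same
containers and file formats the analysis modules consume, so the whole
pipeline is testable without any atlas or reconstruction download.  The
planted structure (arbor labels, cluster labels, topographic map) is
returned alongside the data for recovery tests.

Default conditions: planted arbors are isotropic Gaussian clouds of 60
nodes with within-arbor radius ~50 µm whose centroids sit >= 5x that
radius apart (400 µm), joined by long sparse bridge paths; population
archetypes are disjoint-ish target sets with per-cell target dropout;
mesoscale NPV rows are population mean axon lengths with multiplicative
log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AnnotationVolume, RegionOntology
from .swc import (
    SWC_COLUMNS,
    NeuronMorphology,
    TYPE_AXON,
    TYPE_BASAL_DENDRITE,
    TYPE_SOMA,
)

# -- toy atlas -----------------------------------------------------------

#: (id, acronym, name, parent, curated)
_TOY_REGIONS = [
    (1, "BRAIN", "whole brain", -1, False),
    (2, "CTX", "cortical slab", 1, False),
    (10, "CTX-A", "cortical area A", 2, True),
    (20, "CTX-B", "cortical area B", 2, True),
    # layers of each area (leaves rolling up to the curated areas)
    *[
        (10 + i, f"CTX-A-L{name}", f"area A layer {name}", 10, False)
        for i, name in enumerate(["1", "2/3", "4", "5", "6", "wm"], start=1)
    ],
    *[
        (20 + i, f"CTX-B-L{name}", f"area B layer {name}", 20, False)
        for i, name in enumerate(["1", "2/3", "4", "5", "6", "wm"], start=1)
    ],
    (30, "THAL", "thalamus box", 1, True),
    (40, "STRI", "striatum box", 1, True),
    (50, "GPE-box", "pallidum box", 1, True),
    (60, "SNR-box", "nigra box", 1, True),
    (70, "MB-box", "midbrain box", 1, True),
    (80, "MY-box", "medulla box", 1, True),
]

#: Layer thicknesses in µm, pia downward (L1, L2/3, L4, L5, L6, white matter).
LAYER_THICKNESS_UM = (100.0, 150.0, 100.0, 150.0, 150.0, 100.0)


@dataclass
class ToyAtlasSpec:
    seed: int = 0
    resolution: float = 25.0  # µm per voxel, isotropic
    shape: tuple = (80, 60, 80)  # (AP, SI, LR) voxels


def make_toy_atlas(spec: ToyAtlasSpec | None = None):
    """Layered cortical slab over six subcortical boxes, plus ontology.

    The slab occupies the superficial band of the superior-inferior axis
    with six layers + white matter; two cortical areas split the
    anterior-posterior extent.  Six labelled boxes tile the deep half.
    The same labels span both hemispheres; the midline sits at the
    centre of the left-right axis.  Deterministic per spec.
    """
    spec = spec or ToyAtlasSpec()
    res = float(spec.resolution)
    labels = np.zeros(spec.shape, dtype=np.int32)
    nx, ny, nz = spec.shape

    # cortical slab along y (superior-inferior)
    y0 = 0
    half_x = nx // 2
    for li, thick in enumerate(LAYER_THICKNESS_UM, start=1):
        y1 = y0 + max(1, int(round(thick / res)))
        labels[:half_x, y0:y1, :] = 10 + li
        labels[half_x:, y0:y1, :] = 20 + li
        y0 = y1

    # subcortical boxes tiling the deep half: 3 along AP x 2 along SI
    deep0 = y0 + max(1, ny // 12)
    box_ids = [30, 40, 50, 60, 70, 80]
    x_edges = np.linspace(0, nx, 4).astype(int)
    y_edges = np.linspace(deep0, ny, 3).astype(int)
    b = 0
    for yi in range(2):
        for xi in range(3):
            labels[
                x_edges[xi]:x_edges[xi + 1], y_edges[yi]:y_edges[yi + 1], :
            ] = box_ids[b]
            b += 1

    records = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in _TOY_REGIONS],
        columns=["id", "acronym", "name", "parent"],
    )
    curated = [r[0] for r in _TOY_REGIONS if r[4]]
    ontology = RegionOntology(records, curated)
    volume = AnnotationVolume(
        labels,
        resolution=res,
        midline=nz * res / 2.0,
        axis_order="ap-si-lr",
        lr_axis=2,
    )
    return volume, ontology


def cortical_slab_geometry(spec: ToyAtlasSpec | None = None) -> dict:
    """Pia/white-matter depths of the toy slab (µm), for normalized depth."""
    spec = spec or ToyAtlasSpec()
    res = float(spec.resolution)
    voxels = [max(1, int(round(t / res))) for t in LAYER_THICKNESS_UM]
    edges = np.concatenate([[0], np.cumsum(voxels)]) * res
    return {
        "pia_depth": 0.0,
        "layer_edges_um": edges,
        "wm_top_um": float(edges[-2]),
        "thickness_um": float(edges[-2]),  # pia to top of white matter
    }


# -- planted-arbor neurons ----------------------------------------------


@dataclass
class NeuronSpec:
    seed: int = 0
    soma: tuple = (500.0, 800.0, 500.0)
    arbor_centroids: tuple = ((500.0, 800.0, 500.0), (900.0, 800.0, 500.0))
    nodes_per_arbor: int = 60
    arbor_radius: float = 50.0  # ~sd of node cloud about its centroid
    bridge_nodes: int = 3
    with_dendrite: bool = False


def planted_centroids(
    rng: np.random.Generator,
    k: int,
    soma,
    base_distance: float = 450.0,
    min_separation: float = 250.0,
    max_tries: int = 1000,
) -> tuple:
    """Arbor centroids around a soma with guaranteed mutual separation.

    The first centroid is the soma itself; the rest sit ``base_distance``
    (±20%) away along rejection-sampled directions until every pair of
    centroids is at least ``min_separation`` apart (default 5x the 50-µm
    within-arbor radius).
    """
    soma = np.asarray(soma, dtype=float)
    centroids = [soma]
    for _ in range(k - 1):
        for _try in range(max_tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = soma + direction * base_distance * rng.uniform(0.8, 1.2)
            if all(
                np.linalg.norm(cand - c) >= min_separation for c in centroids
            ):
                centroids.append(cand)
                break
        else:
            raise RuntimeError("could not place separated centroids")
    return tuple(map(tuple, centroids))


def make_neuron(spec: NeuronSpec):
    """Random tree with planted multi-arbor axon; returns ground truth.

    Each arbor is a locally dense subtree (nodes drawn around its
    centroid, attached to their nearest predecessor); arbors are joined
    by sparse bridge paths whose soma-side segment is the longest, so the
    minimum-similarity cut severs each bridge at its first segment and
    bridge nodes belong with the arbor they lead to.  Returns
    (NeuronMorphology, ground-truth arbor label per node id).
    """
    rng = np.random.default_rng(spec.seed)
    centroids = np.asarray(spec.arbor_centroids, dtype=float)
    soma = np.asarray(spec.soma, dtype=float)

    rows = []  # (id, type, x, y, z, radius, parent)
    truth: dict = {}
    next_id = 1

    def add(ntype, pos, parent, label):
        nonlocal next_id
        rows.append(
            (next_id, ntype, pos[0], pos[1], pos[2], 0.5, parent)
        )
        truth[next_id] = label
        next_id += 1
        return next_id - 1

    soma_id = add(TYPE_SOMA, soma, -1, 0)

    arbor_positions: list = []
    arbor_ids: list = []
    for a, centroid in enumerate(centroids):
        if a == 0:
            entry_id, entry_pos = soma_id, soma
        else:
            # bridge from a node of the soma arbor toward this centroid;
            # the first (soma-side) gap is the longest segment
            src = rng.integers(0, len(arbor_positions[0]))
            start = arbor_positions[0][src]
            parent = arbor_ids[0][src]
            fracs = np.linspace(0.45, 1.0, max(1, spec.bridge_nodes))
            for f in fracs:
                pos = start + f * (centroid - start)
                parent = add(TYPE_AXON, pos, parent, a)
            entry_id, entry_pos = parent, centroid
        positions = [np.asarray(entry_pos, dtype=float)]
        ids = [entry_id]
        for _ in range(spec.nodes_per_arbor - 1):
            pos = centroid + rng.normal(scale=spec.arbor_radius / 2.0, size=3)
            d = np.linalg.norm(np.asarray(positions) - pos, axis=1)
            nearest = int(np.argmin(d))
            nid = add(TYPE_AXON, pos, ids[nearest], a)
            positions.append(pos)
            ids.append(nid)
        arbor_positions.append(np.asarray(positions))
        arbor_ids.append(ids)

    if spec.with_dendrite:
        parent = soma_id
        for i in range(8):
            pos = soma + rng.normal(scale=20.0, size=3)
            parent = add(TYPE_BASAL_DENDRITE, pos, parent, 0)

    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    neuron = NeuronMorphology(nodes, {"source": "synthetic", "lr_axis": 2})
    return neuron, truth


# -- planted projection populations --------------------------------------


@dataclass
class PopulationSpec:
    seed: int = 0
    #: archetype name -> {curated structure id: mean axon length, mm}
    archetypes: dict = field(
        default_factory=lambda: {
            "A": {30: 8.0, 40: 5.0, 70: 3.0},
            "B": {40: 6.0, 50: 9.0, 80: 4.0},
            "C": {30: 4.0, 60: 7.0, 80: 6.0},
        }
    )
    cells_per_archetype: int = 20
    dropout: float = 0.25  # per-target omission probability per cell
    length_noise_sd: float = 0.3  # log-normal sigma on kept target lengths
    npv_noise_sd: float = 0.2  # log-normal sigma on mesoscale NPV rows
    experiments_per_archetype: int = 3
    hemisphere: str = "ipsi"


def make_population(spec: PopulationSpec | None = None):
    """Cells drawing target subsets from archetypes, plus a mesoscale table.

    Each cell keeps each archetype target independently with probability
    1 - dropout (at least one target always kept) and draws its axon
    length around the archetype mean with multiplicative log-normal
    noise; dropped targets get zero.  Mesoscale NPV rows per archetype
    are the population mean axon length scaled to the NPV range with
    multiplicative noise.  Returns (cells DataFrame of lengths in mm,
    archetype label per cell, mesoscale NPV DataFrame with an
    ``archetype`` column).
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(spec.seed)
    structures = sorted({s for t in spec.archetypes.values() for s in t})
    columns = [(s, spec.hemisphere) for s in structures]

    cell_rows, labels, index = [], [], []
    for name, targets in spec.archetypes.items():
        for c in range(spec.cells_per_archetype):
            keep = {
                s: rng.random() >= spec.dropout for s in targets
            }
            if not any(keep.values()):
                keep[rng.choice(sorted(targets))] = True
            row = {}
            for s in structures:
                if s in targets and keep[s]:
                    row[(s, spec.hemisphere)] = targets[s] * rng.lognormal(
                        0.0, spec.length_noise_sd
                    )
                else:
                    row[(s, spec.hemisphere)] = 0.0
            cell_rows.append(row)
            labels.append(name)
            index.append(f"{name}-{c:03d}")
    cells = pd.DataFrame(cell_rows, index=index)[columns]
    cells.columns = pd.MultiIndex.from_tuples(
        cells.columns, names=["structure", "hemisphere"]
    )

    exp_rows, exp_index, exp_arch = [], [], []
    for name, targets in spec.archetypes.items():
        pop_mean = {
            s: (targets[s] * (1.0 - spec.dropout) if s in targets else 0.0)
            for s in structures
        }
        for e in range(spec.experiments_per_archetype):
            row = {
                (s, spec.hemisphere): (
                    pop_mean[s] / 100.0 * rng.lognormal(0.0, spec.npv_noise_sd)
                    if pop_mean[s] > 0
                    else 0.0
                )
                for s in structures
            }
            exp_rows.append(row)
            exp_index.append(f"meso-{name}-{e}")
            exp_arch.append(name)
    mesoscale = pd.DataFrame(exp_rows, index=exp_index)[columns]
    mesoscale.columns = pd.MultiIndex.from_tuples(
        mesoscale.columns, names=["structure", "hemisphere"]
    )
    mesoscale["archetype"] = exp_arch
    return cells, np.asarray(labels), mesoscale


# -- planted feature sets for consensus co-clustering --------------------


@dataclass
class FeatureSetSpec:
    seed: int = 0
    n_clusters: int = 3
    cells_per_cluster: int = 20
    n_sets: int = 4
    n_features: tuple = (8, 3, 6, 6)
    separation: float = 6.0  # cluster centre scale, in within-cluster sd units
    n_outliers: int = 0
    outlier_scale: float = 12.0


def make_feature_sets(spec: FeatureSetSpec | None = None):
    """Planted-cluster feature sets sharing one label vector.

    Each set places its cluster centres on scaled coordinate directions
    so every set carries the same planted partition; unit-variance
    Gaussian noise is added per cell.  Optional outliers sit far from
    every centre (label -1).  Returns (list of matrices, labels).
    """
    spec = spec or FeatureSetSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_clusters * spec.cells_per_cluster
    labels = np.repeat(np.arange(spec.n_clusters), spec.cells_per_cluster)
    sets = []
    for si in range(spec.n_sets):
        p = spec.n_features[si % len(spec.n_features)]
        centres = rng.normal(size=(spec.n_clusters, p))
        centres /= np.linalg.norm(centres, axis=1, keepdims=True)
        centres *= spec.separation
        X = centres[labels] + rng.normal(size=(n, p))
        if spec.n_outliers:
            unit_centres = centres / np.linalg.norm(centres, axis=1, keepdims=True)
            out_rows = []
            for _ in range(spec.n_outliers):
                # keep planted outliers away from every cluster direction
                for _try in range(1000):
                    u = rng.normal(size=p)
                    u /= np.linalg.norm(u)
                    if np.max(unit_centres @ u) < 0.4:
                        break
                out_rows.append(u * spec.outlier_scale)
            X = np.vstack([X, out_rows])
        sets.append(X)
    if spec.n_outliers:
        labels = np.concatenate([labels, -np.ones(spec.n_outliers, dtype=int)])
    return sets, labels


# -- topographic populations ---------------------------------------------


@dataclass
class TopographySpec:
    seed: int = 0
    n_cells: int = 40
    soma_box: tuple = ((0.0, 0.0, 0.0), (600.0, 400.0, 500.0))
    #: linear soma -> arbor-centre map (3x3) plus offset
    A: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    offset: tuple = (2000.0, 1500.0, 0.0)
    noise_sigma: float = 30.0  # µm, isotropic on arbor centres
    overlap_decay_um: float | None = None  # planted exp(-d/λ) pair overlap


def make_topographic_population(spec: TopographySpec | None = None):
    """Somas with arbor centres at A @ soma + offset + noise.

    Returns a dict with ``somas``, ``centres``, the planted map ``A`` /
    ``offset``, and (when ``overlap_decay_um`` is set) a planted pairwise
    ``overlaps`` matrix exp(-d_soma / λ) with multiplicative noise, for
    decay-rate recovery tests.
    """
    spec = spec or TopographySpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = np.asarray(spec.soma_box[0]), np.asarray(spec.soma_box[1])
    somas = rng.uniform(lo, hi, size=(spec.n_cells, 3))
    A = np.asarray(spec.A, dtype=float)
    centres = somas @ A.T + np.asarray(spec.offset) + rng.normal(
        scale=spec.noise_sigma, size=(spec.n_cells, 3)
    )
    out = {"somas": somas, "centres": centres, "A": A, "offset": np.asarray(spec.offset)}
    if spec.overlap_decay_um is not None:
        d = np.linalg.norm(somas[:, None, :] - somas[None, :, :], axis=2)
        noise = rng.lognormal(0.0, 0.1, size=d.shape)
        noise = np.sqrt(noise * noise.T)  # keep the matrix symmetric
        ov = np.exp(-d / spec.overlap_decay_um) * noise
        np.fill_diagonal(ov, 1.0)
        out["overlaps"] = np.clip(ov, 0.0, 1.0)
    return out
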