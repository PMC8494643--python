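"""Arbor overlap, spatial-regularity fits, and soma→arbor topography.

Pairs of neurons projecting to a common target show a regular spatial
organization: the centre-to-centre distance of their axon arbors grows
proportionally with their soma-to-soma distance, while the overlap of
the arbors decays exponentially with it.  Overlap is measured as a
length-weighted Dice score of voxelized arbor cable maps on a coarse
grid (50 µm default).  The soma→arbor-centre topographic map is
summarized by a 3x3 Pearson correlation matrix between soma axes and
arbor-centre axes, the best axis pairing (an exact assignment over the
six axis permutations maximizing total |correlation|) and the sign of
each paired correlation — recovering, e.g., a preserved, flipped or
rotated topography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd


@dataclass
class ArborOccupancy:
    """Voxelized cable-length map of one arbor on a shared coarse grid."""

    arbor_id: str
    voxels: dict  # (i, j, k) -> cable length
    grid_size: float = 50.0
    centre: np.ndarray | None = None
    soma: np.ndarray | None = None

    def mass(self) -> float:
        return float(sum(self.voxels.values()))


def voxelize_arbor(
    coords: np.ndarray,
    segments: np.ndarray,
    grid_size: float = 50.0,
    arbor_id: str = "",
    soma=None,
) -> ArborOccupancy:
    """Bin each segment's cable length into the voxel of its midpoint."""
    coords = np.asarray(coords, dtype=float)
    segments = np.asarray(segments, dtype=int)
    voxels: dict = {}
    if len(segments):
        p0, p1 = coords[segments[:, 0]], coords[segments[:, 1]]
        mids = (p0 + p1) / 2.0
        lengths = np.linalg.norm(p1 - p0, axis=1)
        keys = np.floor(mids / grid_size).astype(int)
        for key, ln in zip(map(tuple, keys), lengths):
            voxels[key] = voxels.get(key, 0.0) + float(ln)
    centre = coords.mean(axis=0) if len(coords) else None
    return ArborOccupancy(
        arbor_id=arbor_id,
        voxels=voxels,
        grid_size=grid_size,
        centre=centre,
        soma=None if soma is None else np.asarray(soma, dtype=float),
    )


def overlap_score(a: ArborOccupancy, b: ArborOccupancy) -> float:
    """Length-weighted Dice overlap: 2 Σ min(a, b) / (Σ a + Σ b), in [0, 1]."""
    if a.grid_size != b.grid_size:
        raise ValueError("occupancy maps are on different grids")
    total = a.mass() + b.mass()
    if total == 0:
        return 0.0
    inter = sum(
        min(v, b.voxels[key]) for key, v in a.voxels.items() if key in b.voxels
    )
    return float(2.0 * inter / total)


def overlap_matrix(occupancies) -> np.ndarray:
    occ = list(occupancies)
    n = len(occ)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = overlap_score(occ[i], occ[j])
    return out


@dataclass
class DistanceOverlapFit:
    pairs: pd.DataFrame
    slope: float = np.nan  # centre distance vs soma distance, free intercept
    intercept: float = np.nan
    slope_zero_intercept: float = np.nan
    r2_distance: float = np.nan
    decay_amplitude: float = np.nan  # overlap ≈ a * exp(-b * soma distance)
    decay_rate: float = np.nan
    r2_decay: float = np.nan


def distance_overlap_relation(
    somas: np.ndarray,
    centres: np.ndarray,
    occupancies=None,
    overlaps: np.ndarray | None = None,
) -> DistanceOverlapFit:
    """Per-pair distances and overlap, with proportionality and decay fits.

    For every neuron pair: soma-to-soma distance, arbor centre-to-centre
    distance and arbor overlap (from ``occupancies`` maps, or a
    precomputed symmetric ``overlaps`` matrix).  Fits (i) least-squares
    centre distance vs soma distance, both free- and zero-intercept, and
    (ii) a log-linear exponential decay overlap = a exp(-b d_soma) on
    pairs with positive overlap (skipped with fewer than 2 such pairs).
    """
    somas = np.asarray(somas, dtype=float)
    centres = np.asarray(centres, dtype=float)
    occ = list(occupancies) if occupancies is not None else None
    n = len(somas)
    if n * (n - 1) // 2 < 10:
        warnings.warn("fewer than 10 pairs; fits may be unstable")

    def _overlap(i, j):
        if overlaps is not None:
            return float(overlaps[i, j])
        if occ is not None:
            return overlap_score(occ[i], occ[j])
        return np.nan

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                (
                    i,
                    j,
                    float(np.linalg.norm(somas[i] - somas[j])),
                    float(np.linalg.norm(centres[i] - centres[j])),
                    _overlap(i, j),
                )
            )
    pairs = pd.DataFrame(
        rows, columns=["i", "j", "soma_distance", "centre_distance", "overlap"]
    )
    fit = DistanceOverlapFit(pairs=pairs)

    x = pairs["soma_distance"].to_numpy()
    y = pairs["centre_distance"].to_numpy()
    if len(x) >= 2 and np.var(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
        fit.slope, fit.intercept = float(slope), float(intercept)
        pred = slope * x + intercept
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        fit.r2_distance = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        fit.slope_zero_intercept = float(np.dot(x, y) / np.dot(x, x))

    pos = pairs.dropna(subset=["overlap"])
    pos = pos[pos["overlap"] > 0]
    if len(pos) >= 2 and np.var(pos["soma_distance"]) > 0:
        ln_ov = np.log(pos["overlap"].to_numpy())
        b, ln_a = np.polyfit(pos["soma_distance"].to_numpy(), ln_ov, 1)
        fit.decay_rate = float(-b)
        fit.decay_amplitude = float(np.exp(ln_a))
        pred = ln_a + b * pos["soma_distance"].to_numpy()
        ss_res = float(np.sum((ln_ov - pred) ** 2))
        ss_tot = float(np.sum((ln_ov - ln_ov.mean()) ** 2))
        fit.r2_decay = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return fit


def domain_partition(
    overlap: np.ndarray,
    n_domains: int | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Group arbors into spatial domains by agglomerative clustering on
    1 - overlap (average linkage)."""
    from sklearn.cluster import AgglomerativeClustering

    overlap = np.asarray(overlap, dtype=float)
    d = 1.0 - overlap
    np.fill_diagonal(d, 0.0)
    if n_domains is None and threshold is None:
        threshold = 0.5
    if n_domains is not None:
        agg = AgglomerativeClustering(
            n_clusters=n_domains, metric="precomputed", linkage="average"
        )
    else:
        agg = AgglomerativeClustering(
            n_clusters=None,
            distance_threshold=threshold,
            metric="precomputed",
            linkage="average",
        )
    return agg.fit_predict(d)


@dataclass
class TopographyMap:
    """Axis-pairing summary of a soma→arbor-centre topographic map."""

    correlation: np.ndarray  # 3x3, soma axis x arbor axis
    pairing: tuple  # pairing[soma_axis] = arbor axis (a permutation)
    signs: tuple  # sign of the chosen correlation per soma axis
    unpaired: list = field(default_factory=list)


def topography_map(somas: np.ndarray, arbor_centres: np.ndarray) -> TopographyMap:
    """Correlate soma axes with arbor-centre axes and pair them.

    Pearson correlation is computed for each of the 9 axis pairs; the
    pairing is the axis permutation maximizing the summed |correlation|
    (exact over the 6 permutations), and each pair carries the sign of
    its correlation.  Axes with degenerate variance are left unpaired.
    """
    somas = np.asarray(somas, dtype=float)
    arbor_centres = np.asarray(arbor_centres, dtype=float)
    if len(somas) < 5:
        raise ValueError("need at least 5 cells for a topography map")
    corr = np.zeros((3, 3))
    degenerate = set()
    for a in range(3):
        if np.var(somas[:, a]) == 0:
            degenerate.add(("soma", a))
        if np.var(arbor_centres[:, a]) == 0:
            degenerate.add(("arbor", a))
    for a in range(3):
        for b in range(3):
            if ("soma", a) in degenerate or ("arbor", b) in degenerate:
                corr[a, b] = np.nan
                continue
            corr[a, b] = np.corrcoef(somas[:, a], arbor_centres[:, b])[0, 1]
    if degenerate:
        warnings.warn(f"degenerate variance on axes: {sorted(degenerate)}")

    best_perm, best_total = None, -np.inf
    for perm in permutations(range(3)):
        vals = [corr[a, perm[a]] for a in range(3)]
        total = sum(abs(v) for v in vals if np.isfinite(v))
        if total > best_total:
            best_total, best_perm = total, perm
    signs = tuple(
        int(np.sign(corr[a, best_perm[a]])) if np.isfinite(corr[a, best_perm[a]]) else 0
        for a in range(3)
    )
    unpaired = [a for a in range(3) if not np.isfinite(corr[a, best_perm[a]])]
    return TopographyMap(
        correlation=corr, pairing=best_perm, signs=signs, unpaired=unpaired
    )
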