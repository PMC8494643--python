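"""Anchor-based cortical surface geometry.

The cortex is divided into consecutive coronal slices (100 µm thick by
default).  Anchor points are sampled evenly along the outer border of
each slice; each anchor carries an inward unit normal (perpendicular to
the local surface, in-slice) and a surface area estimated from the
distance to its neighbour anchors times the slice thickness.  Nodes are
assigned to their nearest anchor; cortical depth is the projection of
the node offset onto the anchor normal, and a node's surface position is
its projection back along that normal.  These assignments support arbor
2D area, arbor radius, vertical (laminar) profiles, tangential span and
apical-dendrite alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .swc import NeuronMorphology, TYPE_APICAL_DENDRITE


@dataclass
class AnchorSet:
    """Evenly spaced surface anchors with inward normals and areas."""

    positions: np.ndarray  # (n, 3) µm
    normals: np.ndarray  # (n, 3) unit, pointing into the brain
    areas: np.ndarray  # (n,) µm²
    slice_index: np.ndarray  # (n,) int
    slice_thickness: float = 100.0

    def __post_init__(self):
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("anchor normals must be unit length")
        if np.any(self.areas <= 0):
            raise ValueError("anchor areas must be positive")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class DepthAssignment:
    """Per-node nearest anchor, depth along its normal, surface position."""

    anchor_id: np.ndarray  # (n,) int
    depth: np.ndarray  # (n,) µm
    surface_points: np.ndarray  # (n, 3) µm
    normalized_depth: np.ndarray | None = None  # in [0, 1] when thickness known


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Points at ≈ spacing arc-length intervals along a polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return points[:1]
    n = max(1, int(np.ceil(total / spacing - 1e-9)))
    targets = np.linspace(0.0, total, n + 1)
    out = np.empty((len(targets), 3))
    j = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    denom = np.where(seg[j] == 0, 1.0, seg[j])
    frac = (targets - cum[j]) / denom
    out = points[j] + frac[:, None] * (points[j + 1] - points[j])
    return out


def build_anchors(
    border_polylines,
    interior_point: np.ndarray,
    slice_thickness: float = 100.0,
    spacing: float = 50.0,
    slice_axis: int = 0,
) -> AnchorSet:
    """Sample anchors along per-slice outer border polylines.

    Parameters
    ----------
    border_polylines:
        Sequence of (m_i, 3) arrays, one ordered polyline per coronal
        slice, tracing the outer cortical border within the slice plane.
    interior_point:
        A point inside the brain used to orient normals inward.
    slice_thickness, spacing:
        Slice thickness and target arc-length between anchors, µm.
    slice_axis:
        Axis perpendicular to the slicing planes (anterior-posterior by
        the package's axis convention).

    Each anchor's normal is the in-slice perpendicular of the local
    border tangent (from its ±1 neighbours), oriented toward the
    interior; its area is the mean distance to its neighbour anchors
    times the slice thickness.
    """
    interior_point = np.asarray(interior_point, dtype=float)
    positions, normals, areas, slices = [], [], [], []
    for si, poly in enumerate(border_polylines):
        poly = np.asarray(poly, dtype=float)
        if len(poly) == 0:
            raise ValueError(f"slice {si}: empty border polyline")
        pts = _resample_polyline(poly, spacing)
        if len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) < 1e-9:
            pts = pts[:-1]  # closed border: do not duplicate the start anchor
        n_pts = len(pts)
        for i in range(n_pts):
            lo, hi = max(0, i - 1), min(n_pts - 1, i + 1)
            tangent = pts[hi] - pts[lo]
            tangent[slice_axis] = 0.0  # normals are in-plane (coronal slicing)
            tnorm = np.linalg.norm(tangent)
            if tnorm == 0:
                tangent = np.array([0.0, 1.0, 0.0])
                tangent[slice_axis] = 0.0
                tnorm = np.linalg.norm(tangent)
            tangent /= tnorm
            in_plane = [a for a in range(3) if a != slice_axis]
            normal = np.zeros(3)
            normal[in_plane[0]] = -tangent[in_plane[1]]
            normal[in_plane[1]] = tangent[in_plane[0]]
            if np.dot(interior_point - pts[i], normal) < 0:
                normal = -normal
            neigh = []
            if i > 0:
                neigh.append(np.linalg.norm(pts[i] - pts[i - 1]))
            if i < n_pts - 1:
                neigh.append(np.linalg.norm(pts[i] - pts[i + 1]))
            mean_gap = float(np.mean(neigh)) if neigh else spacing
            positions.append(pts[i])
            normals.append(normal)
            areas.append(mean_gap * slice_thickness)
            slices.append(si)
    return AnchorSet(
        positions=np.asarray(positions),
        normals=np.asarray(normals),
        areas=np.asarray(areas),
        slice_index=np.asarray(slices, dtype=int),
        slice_thickness=slice_thickness,
    )


def flat_slab_anchors(
    x_range,
    z_range,
    surface_y: float = 0.0,
    slice_thickness: float = 100.0,
    spacing: float = 50.0,
) -> AnchorSet:
    """Anchors for a flat synthetic slab whose surface is the y=surface_y
    plane, with the inward normal along +y.  One 'slice' per x interval."""
    xs = np.arange(x_range[0], x_range[1], slice_thickness) + slice_thickness / 2
    zs = np.arange(z_range[0], z_range[1], spacing) + spacing / 2
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    n = gx.size
    positions = np.column_stack(
        [gx.ravel(), np.full(n, surface_y), gz.ravel()]
    )
    normals = np.tile([0.0, 1.0, 0.0], (n, 1))
    areas = np.full(n, spacing * slice_thickness)
    slice_index = np.repeat(np.arange(len(xs)), len(zs))
    return AnchorSet(positions, normals, areas, slice_index, slice_thickness)


def assign_depth(
    points: np.ndarray,
    anchors: AnchorSet,
    cortical_thickness: float | None = None,
) -> DepthAssignment:
    """Assign each point to its nearest anchor and measure depth.

    Depth is the signed projection of (point - anchor) onto the anchor's
    inward normal; the surface position is the point projected back to
    zero depth.  ``cortical_thickness`` (µm, pia to white matter) enables
    normalized depth in [0, 1].
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(anchors.positions)
    _, idx = tree.query(points)
    offsets = points - anchors.positions[idx]
    depth = np.einsum("ij,ij->i", offsets, anchors.normals[idx])
    surface = points - depth[:, None] * anchors.normals[idx]
    ndepth = None
    if cortical_thickness is not None:
        ndepth = np.clip(depth / cortical_thickness, 0.0, 1.0)
    return DepthAssignment(
        anchor_id=idx, depth=depth, surface_points=surface, normalized_depth=ndepth
    )


def arbor_area_2d(node_rows, assignment: DepthAssignment, anchors: AnchorSet) -> float:
    """2D cortical area of an arbor: summed areas of the distinct anchors
    its nodes occupy (each anchor counted once)."""
    node_rows = np.asarray(node_rows, dtype=int)
    if len(node_rows) == 0:
        return 0.0
    unique_anchors = np.unique(assignment.anchor_id[node_rows])
    return float(anchors.areas[unique_anchors].sum())


def arbor_radius(
    coords: np.ndarray,
    segments: np.ndarray | None = None,
    fraction: float = 0.7,
    criterion: str = "midpoint",
):
    """Arbor centre and enclosing-sphere radius.

    The centre is the node with the shortest average distance to the
    other nodes.  The radius is the smallest r such that at least
    ``fraction`` of the arbor's segments lie within r of the centre,
    where a segment counts as inside by its midpoint (default) or by
    full containment of both endpoints (``criterion='endpoints'``).
    Returns (centre_index, radius).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 1:
        raise ValueError("arbor has no nodes")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    centre = int(np.argmin(d.mean(axis=1)))
    if segments is None or len(segments) == 0:
        dist = d[centre]
        dist = dist[np.arange(len(coords)) != centre]
        if len(dist) == 0:
            return centre, 0.0
    else:
        segments = np.asarray(segments, dtype=int)
        if criterion == "midpoint":
            mids = (coords[segments[:, 0]] + coords[segments[:, 1]]) / 2.0
            dist = np.linalg.norm(mids - coords[centre], axis=1)
        elif criterion == "endpoints":
            dist = np.maximum(
                np.linalg.norm(coords[segments[:, 0]] - coords[centre], axis=1),
                np.linalg.norm(coords[segments[:, 1]] - coords[centre], axis=1),
            )
        else:
            raise ValueError("criterion must be 'midpoint' or 'endpoints'")
    dist = np.sort(dist)
    m = len(dist)
    need = int(np.ceil(fraction * m - 1e-12))
    need = max(1, min(need, m))
    return centre, float(dist[need - 1])


def vertical_profile(
    depths: np.ndarray,
    lengths: np.ndarray,
    bins: int = 20,
    depth_range=None,
) -> tuple:
    """Length-weighted histogram of cable over depth.

    ``depths`` are per-segment (midpoint) depths and ``lengths`` the
    matching cable lengths.  Depths outside ``depth_range`` are clipped
    into the edge bins so the profile conserves total cable length.
    Returns (bin_edges, per-bin summed length).
    """
    depths = np.asarray(depths, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if depth_range is None:
        lo = float(depths.min()) if len(depths) else 0.0
        hi = float(depths.max()) if len(depths) else 1.0
        if hi <= lo:
            hi = lo + 1.0
        depth_range = (lo, hi)
    edges = np.linspace(depth_range[0], depth_range[1], bins + 1)
    clipped = np.clip(depths, depth_range[0], depth_range[1] - 1e-12)
    hist, _ = np.histogram(clipped, bins=edges, weights=lengths)
    return edges, hist


def pooled_profile(profiles) -> np.ndarray:
    """Cumulative vertical profile over cells: element-wise sum."""
    return np.sum(np.asarray(list(profiles), dtype=float), axis=0)


def tangential_span(node_rows, assignment: DepthAssignment) -> float:
    """Maximum pairwise distance between surface-projected node positions."""
    node_rows = np.asarray(node_rows, dtype=int)
    if len(node_rows) < 2:
        return 0.0
    pts = assignment.surface_points[node_rows]
    if len(pts) > 2000:
        from scipy.spatial import ConvexHull

        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    return float(pdist(pts).max())


def shift_apical_to_l1(
    neuron: NeuronMorphology,
    anchors: AnchorSet,
    l1_top_depth: float = 0.0,
) -> NeuronMorphology:
    """Rigidly shift the neuron along the local normal so the shallowest
    apical-dendrite node sits at the top of L1 (depth ``l1_top_depth``)."""
    types = neuron.nodes["type"].to_numpy()
    apical = np.flatnonzero(types == TYPE_APICAL_DENDRITE)
    if len(apical) == 0:
        import warnings

        warnings.warn("no apical dendrite nodes; shift skipped")
        return neuron.copy()
    xyz = neuron.coords()
    assignment = assign_depth(xyz[apical], anchors)
    top = int(np.argmin(assignment.depth))
    delta = assignment.depth[top] - l1_top_depth
    normal = anchors.normals[assignment.anchor_id[top]]
    return neuron.with_coords(xyz - delta * normal)
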