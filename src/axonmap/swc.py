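"""SWC morphology I/O, validation and geometric transforms.

A neuron reconstruction is a rooted tree of typed 3D nodes stored in the
standard 7-column SWC format (``id type x y z radius parent``), with
coordinates in micrometres in a registered atlas space.  This module reads
and writes that format losslessly, runs the topological quality checks a
reconstruction must pass (single tree, no breaks/loops/duplicate ids),
and provides the geometric pre-processing steps applied before any
quantification: pre-order sorting, terminal-branch pruning, anisotropic
resampling, hemisphere mirroring and landmark-based smooth-thin-plate-spline
warping.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]

TYPE_SOMA = 1
TYPE_AXON = 2
TYPE_BASAL_DENDRITE = 3
TYPE_APICAL_DENDRITE = 4

#: Validation issue codes that are warnings only; everything else is an error.
WARNING_CODES = frozenset({"multifurcation", "not-sorted"})

_META_RE = re.compile(r"#\s*([A-Za-z_][\w.\- ]*?)\s*[:=]\s*(.+?)\s*$")


class SWCParseError(ValueError):
    """Raised when an SWC record cannot be parsed; names the line number."""


@dataclass
class ValidationIssue:
    code: str
    node_ids: list

    @property
    def is_warning(self) -> bool:
        return self.code in WARNING_CODES


@dataclass
class ValidationReport:
    """Outcome of the topological QC checks on a morphology.

    ``is_valid`` is true iff every recorded issue is a warning
    (multifurcation, not-sorted); breaks, loops, duplicate ids and
    multiple roots are errors.
    """

    issues: list = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return all(issue.is_warning for issue in self.issues)

    @property
    def errors(self) -> list:
        return [i for i in self.issues if not i.is_warning]

    @property
    def warnings(self) -> list:
        return [i for i in self.issues if i.is_warning]

    def codes(self) -> set:
        return {i.code for i in self.issues}


class NeuronMorphology:
    """A neuron reconstruction: an ordered node table plus metadata.

    Parameters
    ----------
    nodes:
        DataFrame with the seven SWC columns.  Row order is the file order
        and is preserved on round-trip.
    metadata:
        Free-form mapping captured from ``# key: value`` header comments
        (brain id, space name, left-right axis convention, ...).
    """

    def __init__(self, nodes: pd.DataFrame, metadata: dict | None = None):
        nodes = nodes.reset_index(drop=True).copy()
        for col in ("id", "type", "parent"):
            nodes[col] = nodes[col].astype(np.int64)
        for col in ("x", "y", "z", "radius"):
            nodes[col] = nodes[col].astype(float)
        self.nodes = nodes[SWC_COLUMNS]
        self.metadata: dict = dict(metadata or {})

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def coords(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy()

    def id_to_index(self) -> dict:
        return {nid: i for i, nid in enumerate(self.nodes["id"].to_numpy())}

    def parent_index(self) -> np.ndarray:
        """Per-row index of the parent row; -1 for roots/orphans."""
        idx = self.id_to_index()
        parents = self.nodes["parent"].to_numpy()
        return np.array(
            [idx.get(p, -1) if p != -1 else -1 for p in parents], dtype=np.int64
        )

    def root_index(self) -> int:
        roots = np.flatnonzero(self.nodes["parent"].to_numpy() == -1)
        if len(roots) == 0:
            raise ValueError("morphology has no root node")
        return int(roots[0])

    def soma_index(self) -> int:
        soma = np.flatnonzero(self.nodes["type"].to_numpy() == TYPE_SOMA)
        return int(soma[0]) if len(soma) else self.root_index()

    def soma_position(self) -> np.ndarray:
        return self.coords()[self.soma_index()]

    def children_map(self) -> dict:
        kids: dict = {i: [] for i in range(len(self.nodes))}
        for i, p in enumerate(self.parent_index()):
            if p >= 0:
                kids[p].append(i)
        return kids

    def edges(self) -> np.ndarray:
        """(m, 2) array of (parent_row, child_row) for every non-root node."""
        par = self.parent_index()
        child = np.flatnonzero(par >= 0)
        return np.column_stack([par[child], child])

    def segment_lengths(self) -> np.ndarray:
        """Per-row straight-chord length to the parent (0 for roots)."""
        par = self.parent_index()
        xyz = self.coords()
        out = np.zeros(len(xyz))
        has = par >= 0
        out[has] = np.linalg.norm(xyz[has] - xyz[par[has]], axis=1)
        return out

    def total_length(self, types=None) -> float:
        """Total cable length (sum of chords), optionally per node type."""
        seg = self.segment_lengths()
        if types is None:
            return float(seg.sum())
        mask = np.isin(self.nodes["type"].to_numpy(), list(types))
        return float(seg[mask].sum())

    def copy(self) -> "NeuronMorphology":
        return NeuronMorphology(self.nodes.copy(), dict(self.metadata))

    def with_coords(self, xyz: np.ndarray) -> "NeuronMorphology":
        out = self.copy()
        out.nodes[["x", "y", "z"]] = np.asarray(xyz, dtype=float)
        return out


# -- parsing / writing ---------------------------------------------------


def parse_swc(text: str) -> NeuronMorphology:
    """Parse SWC-format text into a :class:`NeuronMorphology`.

    Lines beginning with ``#`` are comments; ``# key: value`` or
    ``# key = value`` headers are captured into metadata.  Records must
    have exactly 7 whitespace-delimited numeric fields; anything else
    raises :class:`SWCParseError` naming the offending line.
    """
    metadata: dict = {}
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _META_RE.match(line)
            if m:
                metadata[m.group(1).strip()] = m.group(2)
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCParseError(
                f"line {lineno}: expected 7 columns, got {len(fields)}"
            )
        try:
            rows.append(
                (
                    int(fields[0]),
                    int(fields[1]),
                    float(fields[2]),
                    float(fields[3]),
                    float(fields[4]),
                    float(fields[5]),
                    int(fields[6]),
                )
            )
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: non-numeric field ({exc})") from None
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    return NeuronMorphology(nodes, metadata)


def write_swc(neuron: NeuronMorphology) -> str:
    """Serialize to SWC text; coordinates/radius as 6-decimal fixed point."""
    buf = io.StringIO()
    for key, value in neuron.metadata.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("# id type x y z radius parent\n")
    for row in neuron.nodes.itertuples(index=False):
        buf.write(
            f"{row.id} {row.type} {row.x:.6f} {row.y:.6f} {row.z:.6f} "
            f"{row.radius:.6f} {row.parent}\n"
        )
    return buf.getvalue()


def read_swc(path) -> NeuronMorphology:
    with open(path) as fh:
        return parse_swc(fh.read())


def save_swc(neuron: NeuronMorphology, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_swc(neuron))


# -- validation ----------------------------------------------------------


def validate(neuron: NeuronMorphology) -> ValidationReport:
    """Run topological QC: a passing morphology is a sorted single tree.

    Nothing is raised; every violation is enumerated in the report with
    one of the codes {multiple-roots, orphan-parent, loop, duplicate-id,
    multifurcation, not-sorted}.
    """
    report = ValidationReport()
    ids = neuron.nodes["id"].to_numpy()
    parents = neuron.nodes["parent"].to_numpy()

    uniq, counts = np.unique(ids, return_counts=True)
    dup = uniq[counts > 1]
    if len(dup):
        report.issues.append(ValidationIssue("duplicate-id", [int(d) for d in dup]))

    id_set = set(int(i) for i in ids)
    orphan = [int(ids[i]) for i, p in enumerate(parents)
              if p != -1 and int(p) not in id_set]
    if orphan:
        report.issues.append(ValidationIssue("orphan-parent", orphan))

    roots = [int(ids[i]) for i in np.flatnonzero(parents == -1)]
    if len(roots) != 1:
        report.issues.append(ValidationIssue("multiple-roots", roots))

    # Nodes not reachable from any root whose ancestry is not broken by an
    # orphan pointer must sit in (or hang off) a parent-pointer cycle.
    idx = {}
    for i, nid in enumerate(ids):  # first occurrence wins on duplicates
        idx.setdefault(int(nid), i)
    kids: dict = {i: [] for i in range(len(ids))}
    orphan_rows = set()
    for i, p in enumerate(parents):
        if p == -1:
            continue
        j = idx.get(int(p))
        if j is None:
            orphan_rows.add(i)
        else:
            kids[j].append(i)
    reachable = set()
    stack = [i for i in np.flatnonzero(parents == -1)] + sorted(orphan_rows)
    while stack:
        i = int(stack.pop())
        if i in reachable:
            continue
        reachable.add(i)
        stack.extend(kids[i])
    looped = [int(ids[i]) for i in range(len(ids)) if i not in reachable]
    if looped:
        report.issues.append(ValidationIssue("loop", looped))

    n_children = np.zeros(len(ids), dtype=int)
    for i, members in kids.items():
        n_children[i] = len(members)
    multi = [int(ids[i]) for i in np.flatnonzero(n_children >= 3)]
    if multi:
        report.issues.append(ValidationIssue("multifurcation", multi))

    unsorted_ids = [
        int(ids[i])
        for i, p in enumerate(parents)
        if p != -1 and int(p) in idx and idx[int(p)] > i
    ]
    if unsorted_ids:
        report.issues.append(ValidationIssue("not-sorted", unsorted_ids))

    return report


# -- tree transforms -----------------------------------------------------


def _require_valid(neuron: NeuronMorphology) -> None:
    report = validate(neuron)
    if not report.is_valid:
        codes = sorted(i.code for i in report.errors)
        raise ValueError(f"morphology fails validation: {codes}")


def sort_tree(neuron: NeuronMorphology) -> NeuronMorphology:
    """Renumber ids in pre-order from the root (root id 1), geometry unchanged."""
    _require_valid(neuron)
    kids = neuron.children_map()
    order = []
    stack = [neuron.root_index()]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(kids[i]))
    new_id = {row: k + 1 for k, row in enumerate(order)}
    par = neuron.parent_index()
    nodes = neuron.nodes.iloc[order].reset_index(drop=True)
    nodes["id"] = np.arange(1, len(order) + 1)
    nodes["parent"] = [
        new_id[par[row]] if par[row] >= 0 else -1 for row in order
    ]
    return NeuronMorphology(nodes, dict(neuron.metadata))


def _unbranched_paths(neuron: NeuronMorphology) -> list:
    """Decompose the tree into maximal unbranched paths.

    Each path is a list of row indices running from a root/branch node to
    the next branch node or tip (inclusive at both ends).
    """
    kids = neuron.children_map()
    root = neuron.root_index()
    anchors = [i for i in range(len(neuron)) if i == root or len(kids[i]) != 1]
    paths = []
    for a in anchors:
        for c in kids[a]:
            path = [a, c]
            while len(kids[path[-1]]) == 1:
                path.append(kids[path[-1]][0])
            paths.append(path)
    return paths


def prune_terminal_branches(
    neuron: NeuronMorphology, min_length: float = 10.0, cascade: bool = False
) -> NeuronMorphology:
    """Remove artifactual short terminal branches.

    A terminal branch runs from a tip back to the nearest branch point
    (exclusive); it is removed when its path length is strictly below
    ``min_length`` (native units).  A single pass by default; with
    ``cascade`` the rule is re-applied until stable.
    """
    _require_valid(neuron)
    current = neuron
    while True:
        kids = current.children_map()
        seg = current.segment_lengths()
        root = current.root_index()
        drop: set = set()
        for path in _unbranched_paths(current):
            tip = path[-1]
            if kids[tip] or tip == root:
                continue  # not a terminal branch
            length = float(seg[path[1:]].sum())
            if length < min_length:
                drop.update(path[1:])  # keep the branch point itself
        if not drop:
            return current
        keep = [i for i in range(len(current)) if i not in drop]
        current = NeuronMorphology(
            current.nodes.iloc[keep], dict(current.metadata)
        )
        if not cascade:
            return current


def resample(neuron: NeuronMorphology, step) -> NeuronMorphology:
    """Re-space nodes along each unbranched path at an anisotropic step.

    ``step`` is a scalar or per-axis triple in native units.  Coordinates
    are scaled by 1/step per axis, each path is re-sampled at unit
    arc-length intervals in that normalized space, and branch points and
    tips are preserved exactly.  Positions and radii are interpolated
    linearly; ids are renumbered in pre-order.
    """
    _require_valid(neuron)
    step = np.broadcast_to(np.asarray(step, dtype=float), (3,))
    if np.any(step <= 0):
        raise ValueError("resample step must be positive")
    xyz = neuron.coords()
    rad = neuron.nodes["radius"].to_numpy()
    types = neuron.nodes["type"].to_numpy()
    root = neuron.root_index()

    new_nodes = []  # (type, x, y, z, radius, parent_newrow)
    new_nodes.append(
        (int(types[root]), *xyz[root], float(rad[root]), -1)
    )
    anchor_new = {root: 0}
    # Process paths outward from the root so every path's start anchor has
    # already been emitted (row order alone need not be topological).
    paths = _unbranched_paths(neuron)
    by_start: dict = {}
    for path in paths:
        by_start.setdefault(path[0], []).append(path)
    ordered, queue = [], [root]
    while queue:
        a = queue.pop(0)
        for path in by_start.get(a, []):
            ordered.append(path)
            queue.append(path[-1])
    for path in ordered:
        pts = xyz[path]
        norm = pts / step
        seg = np.linalg.norm(np.diff(norm, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        n = max(1, math.ceil(total - 1e-9)) if total > 0 else 1
        targets = np.linspace(0.0, total, n + 1)
        prev = anchor_new[path[0]]
        for t in targets[1:-1]:
            j = int(np.searchsorted(cum, t, side="right") - 1)
            j = min(j, len(path) - 2)
            frac = 0.0 if cum[j + 1] == cum[j] else (t - cum[j]) / (cum[j + 1] - cum[j])
            p = pts[j] + frac * (pts[j + 1] - pts[j])
            r = rad[path[j]] + frac * (rad[path[j + 1]] - rad[path[j]])
            new_nodes.append((int(types[path[1]]), *p, float(r), prev))
            prev = len(new_nodes) - 1
        end = path[-1]
        new_nodes.append(
            (int(types[end]), *xyz[end], float(rad[end]), prev)
        )
        anchor_new[end] = len(new_nodes) - 1

    nodes = pd.DataFrame(
        [
            (k + 1, t, x, y, z, r, (p + 1) if p >= 0 else -1)
            for k, (t, x, y, z, r, p) in enumerate(new_nodes)
        ],
        columns=SWC_COLUMNS,
    )
    return sort_tree(NeuronMorphology(nodes, dict(neuron.metadata)))


def flip_to_left(
    neuron: NeuronMorphology, midline: float, lr_axis: int | None = None
) -> NeuronMorphology:
    """Mirror the morphology about the midline when the soma is right of it.

    The left-right axis index comes from ``lr_axis`` or the metadata key
    ``lr_axis``; coordinates below the midline are the left hemisphere.
    Identity when the soma is already left of (or on) the midline.
    """
    if lr_axis is None:
        if "lr_axis" not in neuron.metadata:
            raise ValueError(
                "left-right axis unknown: pass lr_axis or set metadata['lr_axis']"
            )
        lr_axis = int(neuron.metadata["lr_axis"])
    xyz = neuron.coords()
    if xyz[neuron.soma_index(), lr_axis] <= midline:
        return neuron.copy()
    xyz = xyz.copy()
    xyz[:, lr_axis] = 2.0 * midline - xyz[:, lr_axis]
    out = neuron.with_coords(xyz)
    out.metadata["hemisphere"] = "left"
    return out


# -- landmark warping ----------------------------------------------------


@dataclass
class LandmarkWarp:
    """Paired landmark sets defining a smooth thin-plate-spline warp.

    ``smoothing`` is the TPS regularization λ; λ=0 interpolates the
    landmarks exactly.  Requires >= 4 non-coplanar, duplicate-free source
    points for a well-posed 3D warp.
    """

    source_points: np.ndarray
    target_points: np.ndarray
    smoothing: float = 0.0

    def __post_init__(self):
        self.source_points = np.asarray(self.source_points, dtype=float)
        self.target_points = np.asarray(self.target_points, dtype=float)
        if self.source_points.shape != self.target_points.shape:
            raise ValueError("source and target landmark counts differ")
        if self.source_points.ndim != 2 or self.source_points.shape[1] != 3:
            raise ValueError("landmarks must be (n, 3) arrays")
        if len(self.source_points) < 4:
            raise ValueError("need at least 4 landmark pairs for a 3D warp")
        if self.smoothing < 0:
            raise ValueError("smoothing must be non-negative")
        centered = self.source_points - self.source_points.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False)
        scale = max(svals[0], 1.0)
        if svals[2] < 1e-9 * scale:
            raise ValueError("degenerate landmarks: source points are coplanar")
        uniq = np.unique(self.source_points, axis=0)
        if len(uniq) < len(self.source_points):
            raise ValueError("degenerate landmarks: duplicated source points")


def tps_warp(points: np.ndarray, warp: LandmarkWarp) -> np.ndarray:
    """Apply the landmark-fitted smooth TPS interpolant to a point list."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    interp = RBFInterpolator(
        warp.source_points,
        warp.target_points,
        kernel="thin_plate_spline",
        degree=1,
        smoothing=warp.smoothing,
    )
    return interp(points)


def warp_neuron(neuron: NeuronMorphology, warp: LandmarkWarp) -> NeuronMorphology:
    return neuron.with_coords(tps_warp(neuron.coords(), warp))


def read_landmarks(path, smoothing: float = 0.0) -> LandmarkWarp:
    """Read a landmark CSV with columns sx,sy,sz,tx,ty,tz."""
    df = pd.read_csv(path)
    return LandmarkWarp(
        df[["sx", "sy", "sz"]].to_numpy(),
        df[["tx", "ty", "tz"]].to_numpy(),
        smoothing=smoothing,
    )
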