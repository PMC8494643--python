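"""Brain-wide axonal projection quantification.

Single-cell projection strength is measured as axon cable length per
curated structure and hemisphere: every parent-child axon segment is
subdivided at a sub-voxel step and each piece is credited to the structure
containing its midpoint.  A region is a projection *target* of a single
cell when it receives more than 1 mm of axon; projection strength is
ln(axon length in mm) above that threshold and 0 below.  Mesoscale
(population anterograde tracing) experiments are consumed as normalized
projection volume (NPV) tables with strength ln(NPV*100 + 1) and target
threshold 0.2 on the strength scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AnnotationVolume, RegionOntology, IPSI, CONTRA
from .swc import NeuronMorphology, TYPE_AXON

SINGLE_CELL = "single-cell"
MESOSCALE = "mesoscale"

#: Axon length (mm) above which a structure is a single-cell target.
CELL_TARGET_MM = 1.0
#: Mesoscale strength ln(NPV*100+1) above which a structure is a target.
MESOSCALE_TARGET_STRENGTH = 0.2


@dataclass
class ProjectionVector:
    """Per-entity projection values on (curated structure, hemisphere) keys.

    ``values`` maps (structure id, 'ipsi'|'contra') to axon length in mm
    (single cells) or NPV (mesoscale rows).  ``background`` collects axon
    length falling outside every curated structure; it is never a target.
    """

    entity_id: str
    kind: str = SINGLE_CELL
    values: dict = field(default_factory=dict)
    soma_structure: int | None = None
    background: float = 0.0

    def total(self) -> float:
        return float(sum(self.values.values()) + self.background)


def axon_length_by_region(
    neuron: NeuronMorphology,
    volume: AnnotationVolume,
    ontology: RegionOntology,
    substep: float | None = None,
    entity_id: str = "",
) -> ProjectionVector:
    """Credit each axon sub-segment's length to its midpoint's structure.

    Segments are subdivided so every piece is at most ``substep`` µm long
    (default: the smallest voxel dimension); lengths are reported in mm.
    """
    if substep is None:
        substep = float(np.min(volume.resolution))
    if substep <= 0:
        raise ValueError("substep must be positive")
    xyz = neuron.coords()
    par = neuron.parent_index()
    types = neuron.nodes["type"].to_numpy()
    child = np.flatnonzero((par >= 0) & (types == TYPE_AXON))
    vec = ProjectionVector(entity_id=entity_id, kind=SINGLE_CELL)
    soma = neuron.soma_position()
    soma_label = int(volume.region_at(soma))
    if soma_label in ontology.records.index:
        vec.soma_structure = ontology.rollup(soma_label)
    if len(child) == 0:
        warnings.warn("neuron has no axon segments; empty projection vector")
        return vec

    p0 = xyz[par[child]]
    p1 = xyz[child]
    seg_len = np.linalg.norm(p1 - p0, axis=1)
    n_sub = np.maximum(1, np.ceil(seg_len / substep - 1e-12).astype(np.int64))
    seg_idx = np.repeat(np.arange(len(child)), n_sub)
    offsets = np.concatenate([[0], np.cumsum(n_sub)[:-1]])
    j = np.arange(int(n_sub.sum())) - np.repeat(offsets, n_sub)
    t = (j + 0.5) / n_sub[seg_idx]
    mids = p0[seg_idx] + t[:, None] * (p1 - p0)[seg_idx]
    sub_len = (seg_len / n_sub)[seg_idx]

    labels = volume.region_at(mids)
    roll = ontology.rollup_map()
    curated = np.array([roll.get(int(l)) or 0 for l in labels], dtype=np.int64)
    hemi = volume.hemisphere_at(mids, soma)

    df = pd.DataFrame({"structure": curated, "hemi": hemi, "len": sub_len})
    grouped = df.groupby(["structure", "hemi"], sort=True)["len"].sum()
    for (sid, h), length_um in grouped.items():
        mm = float(length_um) / 1000.0
        if sid == 0:
            vec.background += mm
        else:
            vec.values[(int(sid), str(h))] = vec.values.get((int(sid), str(h)), 0.0) + mm
    return vec


def strength_cell(length_mm):
    """Single-cell projection strength: ln(length) above 1 mm, else 0."""
    length_mm = np.asarray(length_mm, dtype=float)
    out = np.where(
        length_mm > CELL_TARGET_MM,
        np.log(np.where(length_mm > 0, length_mm, 1.0)),
        0.0,
    )
    return float(out) if out.ndim == 0 else out


def strength_mesoscale(npv):
    """Mesoscale projection strength ln(NPV*100 + 1)."""
    npv = np.asarray(npv, dtype=float)
    out = np.log(npv * 100.0 + 1.0)
    return float(out) if out.ndim == 0 else out


def is_cell_target(length_mm):
    return np.asarray(length_mm, dtype=float) > CELL_TARGET_MM


def is_mesoscale_target(npv):
    return strength_mesoscale(npv) > MESOSCALE_TARGET_STRENGTH


def count_targets(
    vector: ProjectionVector,
    mode: str = "length",
    neuron: NeuronMorphology | None = None,
    volume: AnnotationVolume | None = None,
    ontology: RegionOntology | None = None,
    threshold: float = CELL_TARGET_MM,
    split_hemispheres: bool = True,
) -> int:
    """Count projection targets by axon length or by axon terminals.

    ``length`` mode counts (structure, hemisphere) entries with more than
    ``threshold`` mm of axon.  ``terminal`` mode counts structures holding
    at least one axon tip (a terminal node, standing in for a bouton) and
    requires the neuron, volume and ontology.
    """
    if mode == "length":
        keys = {
            (sid, h) if split_hemispheres else sid
            for (sid, h), v in vector.values.items()
            if v > threshold
        }
        return len(keys)
    if mode == "terminal":
        if neuron is None or volume is None or ontology is None:
            raise ValueError("terminal mode requires neuron, volume and ontology")
        kids = neuron.children_map()
        types = neuron.nodes["type"].to_numpy()
        tips = [
            i for i in range(len(neuron))
            if types[i] == TYPE_AXON and not kids[i]
        ]
        if not tips:
            return 0
        xyz = neuron.coords()[tips]
        labels = volume.region_at(xyz)
        roll = ontology.rollup_map()
        hemi = volume.hemisphere_at(xyz, neuron.soma_position())
        keys = set()
        for label, h in zip(labels, hemi):
            sid = roll.get(int(label))
            if sid:
                keys.add((sid, str(h)) if split_hemispheres else sid)
        return len(keys)
    raise ValueError(f"unknown mode {mode!r}")


def match_to_mesoscale(
    cells: pd.DataFrame, experiments: pd.DataFrame, ontology: RegionOntology
) -> list:
    """Pair single cells with mesoscale experiments by curated structure.

    ``cells`` needs columns ``id, structure`` (soma structure) and
    ``experiments`` needs ``id, structure`` (injection structure); both may
    carry an optional ``layer`` column which must agree when both rows tag
    it.  Returns all matching (cell id, experiment id) pairs.
    """
    def _roll(df):
        return df["structure"].map(lambda s: ontology.rollup(int(s)))

    cell_struct = _roll(cells)
    exp_struct = _roll(experiments)
    pairs = []
    for ci, cs in zip(cells.index, cell_struct):
        for ei, es in zip(experiments.index, exp_struct):
            if cs is None or es is None or cs != es:
                continue
            cl = cells["layer"].get(ci) if "layer" in cells else None
            el = experiments["layer"].get(ei) if "layer" in experiments else None
            if cl is not None and el is not None and not (
                pd.isna(cl) or pd.isna(el)
            ) and cl != el:
                continue
            pairs.append((cells.at[ci, "id"], experiments.at[ei, "id"]))
    return pairs


# -- projection matrices -------------------------------------------------


def build_matrix(
    vectors, ontology: RegionOntology, structures=None
) -> pd.DataFrame:
    """Assemble projection vectors into a cells x (structure, hemisphere)
    table with columns ``<acronym>_<ipsi|contra>``."""
    if structures is None:
        structures = sorted(
            {sid for vec in vectors for (sid, _h) in vec.values}
        )
    cols = [
        f"{ontology.acronym(sid)}_{h}" for sid in structures for h in (IPSI, CONTRA)
    ]
    rows = {}
    for vec in vectors:
        row = dict.fromkeys(cols, 0.0)
        for (sid, h), v in vec.values.items():
            if sid in structures:
                row[f"{ontology.acronym(sid)}_{h}"] = v
        rows[vec.entity_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "entity"
    return out


def combine_hemispheres(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum the ipsi and contra columns of each structure."""
    base = sorted({c.rsplit("_", 1)[0] for c in matrix.columns})
    out = pd.DataFrame(index=matrix.index)
    for b in base:
        cols = [c for c in matrix.columns if c.rsplit("_", 1)[0] == b]
        out[b] = matrix[cols].sum(axis=1)
    return out
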