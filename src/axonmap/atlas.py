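"""Annotation volume and region ontology.

The reference atlas is a 3D integer label grid (a CCFv3-like annotation
volume) plus a hierarchical region table.  Projection quantification runs
against a curated set of mutually non-overlapping "mid-ontology"
structures: any voxel label is rolled up to its nearest curated ancestor.

Coordinate convention: atlas space in µm, axes ordered
(anterior→posterior, superior→inferior, left→right), origin at the volume
corner, voxel index = floor(coordinate / resolution), 0-based.  The
left-right axis carries the midline used for ipsi/contra calls.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

IPSI = "ipsi"
CONTRA = "contra"


class RegionOntology:
    """Hierarchical region table with a curated non-overlapping structure set.

    Parameters
    ----------
    records:
        DataFrame with columns ``id, acronym, name, parent`` (parent -1 or
        NaN for top-level regions).
    curated:
        Iterable of region ids forming the mid-ontology quantification set;
        members must be mutually non-overlapping (no member is an ancestor
        of another).
    """

    def __init__(self, records: pd.DataFrame, curated=()):
        records = records.copy()
        records["id"] = records["id"].astype(int)
        records["parent"] = (
            records["parent"].fillna(-1).astype(int)
            if "parent" in records
            else -1
        )
        self.records = records.set_index("id", drop=False)
        self.curated: set = {int(c) for c in curated}
        unknown = self.curated - set(self.records.index)
        if unknown:
            raise ValueError(f"curated ids not in ontology: {sorted(unknown)}")
        self._check_forest()
        for rid in self.curated:
            for anc in self.ancestors(rid):
                if anc != rid and anc in self.curated:
                    raise ValueError(
                        f"curated set overlaps: {rid} has curated ancestor {anc}"
                    )
        self._rollup_cache: dict = {}

    def _check_forest(self) -> None:
        for rid in self.records.index:
            seen = set()
            cur = int(rid)
            while cur != -1:
                if cur in seen:
                    raise ValueError(f"ontology parent links contain a cycle at {rid}")
                seen.add(cur)
                cur = int(self.records.at[cur, "parent"]) if cur in self.records.index else -1

    def __contains__(self, region_id: int) -> bool:
        return int(region_id) in self.records.index

    def acronym(self, region_id: int) -> str:
        return str(self.records.at[int(region_id), "acronym"])

    def id_of(self, acronym: str) -> int:
        hits = self.records.index[self.records["acronym"] == acronym]
        if len(hits) != 1:
            raise KeyError(f"acronym {acronym!r} not unique or not found")
        return int(hits[0])

    def parent_of(self, region_id: int) -> int | None:
        p = int(self.records.at[int(region_id), "parent"])
        return None if p == -1 else p

    def ancestors(self, region_id: int):
        """Yield region_id and then each ancestor walking to the root."""
        cur: int | None = int(region_id)
        while cur is not None:
            yield cur
            cur = self.parent_of(cur)

    def rollup(self, region_id: int) -> int | None:
        """Nearest ancestor (or self) in the curated set; None if outside it."""
        region_id = int(region_id)
        if region_id not in self:
            raise KeyError(f"unknown region id {region_id}")
        if region_id in self._rollup_cache:
            return self._rollup_cache[region_id]
        result = None
        for anc in self.ancestors(region_id):
            if anc in self.curated:
                result = anc
                break
        self._rollup_cache[region_id] = result
        return result

    def rollup_map(self) -> dict:
        """label -> curated id (or None) for every region, plus 0 -> None."""
        out = {0: None}
        for rid in self.records.index:
            out[int(rid)] = self.rollup(int(rid))
        return out

    # -- I/O -------------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "regions": self.records[["id", "acronym", "name", "parent"]]
            .to_dict(orient="records"),
            "curated": sorted(self.curated),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "RegionOntology":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["regions"]), payload.get("curated", ()))

    @classmethod
    def from_csv(cls, path) -> "RegionOntology":
        df = pd.read_csv(path)
        curated = df.loc[df.get("curated", False).astype(bool), "id"] if "curated" in df else ()
        return cls(df, curated)


class AnnotationVolume:
    """3D label grid with per-axis µm resolution and a left-right midline."""

    def __init__(
        self,
        labels: np.ndarray,
        resolution,
        midline: float,
        axis_order: str = "ap-si-lr",
        lr_axis: int = 2,
    ):
        self.labels = np.asarray(labels)
        if self.labels.ndim != 3:
            raise ValueError("annotation labels must be a 3D grid")
        self.resolution = np.broadcast_to(
            np.asarray(resolution, dtype=float), (3,)
        ).copy()
        self.axis_order = axis_order
        self.lr_axis = int(lr_axis)
        extent = self.labels.shape[self.lr_axis] * self.resolution[self.lr_axis]
        if not (0.0 <= midline <= extent):
            raise ValueError("midline outside the volume extent")
        self.midline = float(midline)

    @property
    def shape(self):
        return self.labels.shape

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor(points / self.resolution).astype(np.int64)

    def region_at(self, points: np.ndarray) -> np.ndarray:
        """Label of the containing voxel for each point; 0 outside the grid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = self.voxel_of(pts)
        shape = np.asarray(self.labels.shape)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        out = np.zeros(len(vox), dtype=self.labels.dtype)
        if inside.any():
            v = vox[inside]
            out[inside] = self.labels[v[:, 0], v[:, 1], v[:, 2]]
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def hemisphere_at(self, points: np.ndarray, soma_point: np.ndarray):
        """ipsi iff point and soma are on the same side of the midline.

        Points exactly on the midline count as ipsi (deterministic
        tie-break, symmetric under simultaneous mirroring).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        side_p = np.sign(pts[:, self.lr_axis] - self.midline)
        side_s = np.sign(float(np.asarray(soma_point)[self.lr_axis]) - self.midline)
        ipsi = side_p * side_s >= 0
        out = np.where(ipsi, IPSI, CONTRA)
        if np.asarray(points).ndim == 1:
            return str(out[0])
        return out

    # -- I/O: raw binary + JSON sidecar ---------------------------------

    def save(self, prefix) -> None:
        """Write ``<prefix>.raw`` (C-order labels) and ``<prefix>.json``."""
        prefix = Path(prefix)
        self.labels.astype(np.int32).tofile(prefix.with_suffix(".raw"))
        meta = {
            "shape": list(self.labels.shape),
            "dtype": "int32",
            "resolution": self.resolution.tolist(),
            "axis_order": self.axis_order,
            "lr_axis": self.lr_axis,
            "midline": self.midline,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "AnnotationVolume":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        labels = np.fromfile(
            prefix.with_suffix(".raw"), dtype=np.dtype(meta["dtype"])
        ).reshape(meta["shape"])
        return cls(
            labels,
            meta["resolution"],
            meta["midline"],
            axis_order=meta.get("axis_order", "ap-si-lr"),
            lr_axis=meta.get("lr_axis", 2),
        )
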