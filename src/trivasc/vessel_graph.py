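"""Vessel network assembly and segment geometry.

A traced ROI is a set of centerline paths.  ``build_network`` fuses path
endpoints that fall within a merge tolerance into shared nodes (branch
points or endpoints) and turns every path into exactly one segment, giving
the node/segment graph on which all morphometry operates.

Geometry primitives:

* ``arclength`` — summed Euclidean inter-point distance of a polyline (um);
* ``chord`` — straight-line distance between polyline endpoints (um);
* ``tortuosity`` — arclength / chord, the classic dimensionless bending
  index (1 for a straight vessel).  Near-closed segments (chord below a
  small epsilon) have no meaningful ratio; they are flagged undefined
  (NaN) and logged rather than capped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .trace_io import RoiRecord, VesselPath

__all__ = [
    "VesselNode",
    "VesselSegment",
    "VascularNetwork",
    "build_network",
    "arclength",
    "chord",
    "tortuosity",
    "DEFAULT_MERGE_TOL_UM",
    "DEFAULT_CHORD_EPS_UM",
]

#: Endpoint fusion tolerance (um); sub-capillary-diameter, since manual
#: traces of a shared junction rarely coincide exactly.
DEFAULT_MERGE_TOL_UM = 1.0

#: Chord threshold below which tortuosity is undefined (loop / near-loop).
DEFAULT_CHORD_EPS_UM = 1.0


def arclength(polyline: np.ndarray) -> float:
    """Summed Euclidean length of a polyline (um); requires >= 2 points."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("arclength requires a polyline of >= 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def chord(polyline: np.ndarray) -> float:
    """Straight-line distance between the first and last point (um)."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("chord requires a polyline of >= 2 points")
    return float(np.linalg.norm(pts[-1] - pts[0]))


def tortuosity(
    polyline: np.ndarray, chord_eps_um: float = DEFAULT_CHORD_EPS_UM
) -> float:
    """Arclength / chord; NaN when the chord is at or below ``chord_eps_um``."""
    c = chord(polyline)
    if c <= chord_eps_um:
        return float("nan")
    return arclength(polyline) / c


@dataclass
class VesselNode:
    node_id: str
    position: tuple[float, float, float]
    degree: int = 0

    @property
    def kind(self) -> str:
        return "branch" if self.degree >= 3 else "endpoint"


@dataclass
class VesselSegment:
    """One vessel segment: the traced centerline between two nodes."""

    segment_id: str
    polyline: np.ndarray
    end_nodes: tuple[str, str]
    arclength_um: float
    chord_um: float
    tortuosity: float  # NaN when flagged undefined

    @property
    def tortuosity_defined(self) -> bool:
        return np.isfinite(self.tortuosity)


@dataclass
class VascularNetwork:
    """Node/segment graph for one ROI."""

    roi: RoiRecord | None
    nodes: dict[str, VesselNode] = field(default_factory=dict)
    segments: list[VesselSegment] = field(default_factory=list)
    qc_log: list[dict] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def branch_nodes(self) -> list[VesselNode]:
        return [n for n in self.nodes.values() if n.degree >= 3]

    def z_range(self) -> tuple[float, float]:
        if not self.segments:
            raise ValidationError("empty network has no z range")
        zmin = min(float(s.polyline[:, 2].min()) for s in self.segments)
        zmax = max(float(s.polyline[:, 2].max()) for s in self.segments)
        return zmin, zmax


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_network(
    paths: list[VesselPath],
    merge_tol_um: float = DEFAULT_MERGE_TOL_UM,
    roi: RoiRecord | None = None,
    chord_eps_um: float = DEFAULT_CHORD_EPS_UM,
) -> VascularNetwork:
    """Fuse path endpoints into nodes and wrap each path as a segment.

    Endpoint fusion is single-linkage: any two endpoints within
    ``merge_tol_um`` of each other (directly or through a chain of such
    pairs) share one node, whose position is the centroid of its members.
    Interior path points are never fused — only endpoints define nodes.
    """
    if merge_tol_um < 0:
        raise ValidationError("merge_tol_um must be >= 0")
    net = VascularNetwork(roi=roi)
    if not paths:
        return net

    endpoints = np.array(
        [p.points[0] for p in paths] + [p.points[-1] for p in paths], dtype=float
    )
    n_pts = endpoints.shape[0]
    uf = _UnionFind(n_pts)
    tree = cKDTree(endpoints)
    for i, j in tree.query_pairs(merge_tol_um):
        uf.union(i, j)

    cluster_of: dict[int, int] = {}
    members: dict[int, list[int]] = {}
    for i in range(n_pts):
        root = uf.find(i)
        cluster_of[i] = root
        members.setdefault(root, []).append(i)

    node_ids: dict[int, str] = {}
    for k, root in enumerate(sorted(members)):
        nid = f"n{k + 1}"
        node_ids[root] = nid
        centroid = endpoints[members[root]].mean(axis=0)
        net.nodes[nid] = VesselNode(nid, tuple(float(v) for v in centroid))

    npaths = len(paths)
    for idx, path in enumerate(paths):
        a = node_ids[cluster_of[idx]]
        b = node_ids[cluster_of[idx + npaths]]
        length = arclength(path.points)
        ch = chord(path.points)
        tau = length / ch if ch > chord_eps_um else float("nan")
        seg = VesselSegment(
            segment_id=f"s{idx + 1}",
            polyline=path.points,
            end_nodes=(a, b),
            arclength_um=length,
            chord_um=ch,
            tortuosity=tau,
        )
        net.segments.append(seg)
        net.nodes[a].degree += 1
        net.nodes[b].degree += 1
        if not np.isfinite(tau):
            net.qc_log.append(
                {
                    "record": seg.segment_id,
                    "issue": "tortuosity_undefined",
                    "detail": f"chord {ch:.3f} um <= eps {chord_eps_um} um",
                }
            )
    return net
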