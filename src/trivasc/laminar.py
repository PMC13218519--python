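"""Laminar partitioning, per-layer morphometry and axial-vessel taxonomy.

The mouse inner retinal vasculature is organised into three roughly planar
plexuses — superficial (S), intermediate (I) and deep (D) — linked by
axial vessels running through the two gaps between them (SI and ID).
Depth is therefore partitioned into five contiguous compartments
``S < SI < I < ID < D`` (z increasing from vitreal to scleral).

* ``fit_layer_partition`` builds that partition either from explicit cut
  points or automatically, from the depth profile of traced arclength;
* ``assign_layer`` gives every segment the compartment holding the
  majority of its arclength (ties broken toward the shallower layer);
* ``layer_metrics`` / ``pericyte_metrics`` compute the six morphometric
  quantities per compartment and in total;
* ``classify_axial`` sorts inter-plexus chains into the five axial
  classes: SI connecting, ID connecting, SID connecting (all three
  layers), SD connecting (a direct superficial-to-deep bridge skipping
  intermediate contact) and inter-plexus branching (a bifurcation inside
  one of the gaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .errors import DegenerateInputError, ValidationError
from .trace_io import PericyteAnnotation
from .vessel_graph import VascularNetwork, VesselSegment

__all__ = [
    "LAYERS",
    "PLEXUSES",
    "AXIAL_CLASSES",
    "LayerPartition",
    "AxialClassCounts",
    "fit_layer_partition",
    "assign_layer",
    "layer_metrics",
    "pericyte_metrics",
    "compute_metrics",
    "classify_axial",
]

LAYERS = ("S", "SI", "I", "ID", "D")
PLEXUSES = ("S", "I", "D")
AXIAL_CLASSES = (
    "SI_connecting",
    "ID_connecting",
    "SID_connecting",
    "SD_connecting",
    "inter_plexus_branching",
)

#: Half-thickness of a plexus slab around its detected center (um).
DEFAULT_SLAB_HALFWIDTH_UM = 10.0

#: Minimum arclength fraction inside the SI/ID gaps for a segment to be
#: part of a candidate axial chain.
DEFAULT_INTERIOR_FRAC = 0.5

#: Default snap distance from a soma to the nearest vessel point (um).
DEFAULT_SNAP_TOL_UM = 10.0

_TIE_RTOL = 1e-9


@dataclass
class LayerPartition:
    """Five contiguous depth compartments plus the three plexus slabs.

    ``layer_bounds`` maps S/SI/I/ID/D to ``(lo, hi)`` intervals that are
    contiguous, strictly increasing and cover the traced z range;
    ``plexus_slabs`` maps S/I/D to the z intervals regarded as plexus
    membership regions for axial classification.
    """

    layer_bounds: dict[str, tuple[float, float]]
    plexus_slabs: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if tuple(self.layer_bounds) != LAYERS:
            raise ValidationError(f"layer_bounds must have keys {LAYERS} in order")
        prev_hi = None
        for name in LAYERS:
            lo, hi = self.layer_bounds[name]
            if not hi > lo:
                raise ValidationError(f"layer {name}: empty interval ({lo}, {hi})")
            if prev_hi is not None and lo != prev_hi:
                raise ValidationError("layer intervals must be contiguous")
            prev_hi = hi
        for name in PLEXUSES:
            lo, hi = self.plexus_slabs[name]
            if not hi > lo:
                raise ValidationError(f"slab {name}: empty interval")

    @property
    def z_min(self) -> float:
        return self.layer_bounds["S"][0]

    @property
    def z_max(self) -> float:
        return self.layer_bounds["D"][1]

    def layer_of_z(self, z: float) -> str:
        """Compartment containing depth ``z`` (outermost layers extend)."""
        if z >= self.layer_bounds["D"][0]:
            return "D"
        for name in LAYERS[:-1]:
            lo, hi = self.layer_bounds[name]
            if z < hi:
                return name
        return "D"

    def slabs_containing(self, z: float) -> set[str]:
        return {
            name
            for name in PLEXUSES
            if self.plexus_slabs[name][0] <= z <= self.plexus_slabs[name][1]
        }

    def to_dict(self) -> dict:
        return {
            "layer_bounds": {k: list(v) for k, v in self.layer_bounds.items()},
            "plexus_slabs": {k: list(v) for k, v in self.plexus_slabs.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LayerPartition":
        return cls(
            {k: tuple(v) for k, v in data["layer_bounds"].items()},
            {k: tuple(v) for k, v in data["plexus_slabs"].items()},
        )


def partition_from_cuts(
    cuts: tuple[float, float, float, float],
    z_range: tuple[float, float],
    slabs: dict[str, tuple[float, float]] | None = None,
) -> LayerPartition:
    """Partition from 4 interior cut points; slabs default to S/I/D layers."""
    c1, c2, c3, c4 = cuts
    zmin, zmax = z_range
    if not (zmin < c1 < c2 < c3 < c4 < zmax):
        raise ValidationError(
            f"cuts must be strictly increasing inside ({zmin}, {zmax})"
        )
    bounds = {
        "S": (zmin, c1),
        "SI": (c1, c2),
        "I": (c2, c3),
        "ID": (c3, c4),
        "D": (c4, zmax),
    }
    if slabs is None:
        slabs = {"S": bounds["S"], "I": bounds["I"], "D": bounds["D"]}
    return LayerPartition(bounds, slabs)


def fit_layer_partition(
    network: VascularNetwork | None = None,
    mode: str = "auto",
    cuts: tuple[float, float, float, float] | None = None,
    z_range: tuple[float, float] | None = None,
    slab_halfwidth_um: float = DEFAULT_SLAB_HALFWIDTH_UM,
    min_mode_separation_um: float | None = None,
    kde_bandwidth_um: float = 3.0,
) -> LayerPartition:
    """Build the five-compartment depth partition.

    ``explicit`` mode takes 4 interior cut points and a z range (taken
    from the network when omitted).  ``auto`` mode estimates an
    arclength-weighted kernel density over depth, requires exactly three
    well-separated modes (the plexus centers), builds plexus slabs of
    half-width ``slab_halfwidth_um`` around them, and uses the two gaps
    as SI and ID while S and D extend to the stack extremes.
    """
    if mode == "explicit":
        if cuts is None:
            raise ValidationError("explicit mode requires 4 cut points")
        if z_range is None:
            if network is None:
                raise ValidationError("explicit mode needs z_range or a network")
            z_range = network.z_range()
        return partition_from_cuts(tuple(cuts), z_range)
    if mode != "auto":
        raise ValidationError(f"unknown partition mode {mode!r}")
    if network is None or not network.segments:
        raise ValidationError("auto mode requires a non-empty network")

    mids, weights = [], []
    for seg in network.segments:
        pts = seg.polyline
        lens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mids.append((pts[:-1, 2] + pts[1:, 2]) / 2.0)
        weights.append(lens)
    z_mid = np.concatenate(mids)
    w = np.concatenate(weights)
    zmin, zmax = network.z_range() if z_range is None else z_range

    if np.ptp(z_mid) < 1e-9:
        raise DegenerateInputError(
            "auto partition: all arclength at a single depth; supply "
            "explicit cut points instead"
        )
    kde = gaussian_kde(z_mid, bw_method=kde_bandwidth_um / max(np.std(z_mid), 1e-9),
                       weights=w)
    # pad the grid so modes at the stack extremes register as peaks
    pad = 4.0 * kde_bandwidth_um
    grid = np.linspace(zmin - pad, zmax + pad, 1024)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=0.05 * dens.max())
    order = np.argsort(props["prominences"])[::-1]
    if min_mode_separation_um is None:
        min_mode_separation_um = 2.0 * slab_halfwidth_um
    centers: list[float] = []
    for idx in order:
        zc = float(np.clip(grid[peaks[idx]], zmin, zmax))
        if all(abs(zc - c) >= min_mode_separation_um for c in centers):
            centers.append(zc)
    if len(centers) != 3:
        raise DegenerateInputError(
            f"auto partition: found {len(centers)} well-separated depth "
            "modes, need exactly 3; supply explicit cut points instead"
        )
    cs, ci, cd = sorted(centers)
    hw = slab_halfwidth_um
    slabs = {
        "S": (max(zmin, cs - hw), cs + hw),
        "I": (ci - hw, ci + hw),
        "D": (cd - hw, min(zmax, cd + hw)),
    }
    return partition_from_cuts(
        (cs + hw, ci - hw, ci + hw, cd - hw), (zmin, zmax), slabs=slabs
    )


# ---------------------------------------------------------------------------
# Layer assignment
# ---------------------------------------------------------------------------

def _layer_shares(polyline: np.ndarray, partition: LayerPartition) -> np.ndarray:
    """Arclength of ``polyline`` falling in each of the five compartments.

    Each polyline leg's length is apportioned by the fraction of its z
    extent overlapping each compartment; the outermost compartments are
    treated as extending beyond the partition range so shares always sum
    to the total arclength.
    """
    pts = np.asarray(polyline, dtype=float)
    shares = np.zeros(len(LAYERS))
    bounds = []
    for i, name in enumerate(LAYERS):
        lo, hi = partition.layer_bounds[name]
        if i == 0:
            lo = -np.inf
        if i == len(LAYERS) - 1:
            hi = np.inf
        bounds.append((lo, hi))
    for a, b in zip(pts[:-1], pts[1:]):
        leg = float(np.linalg.norm(b - a))
        z1, z2 = sorted((a[2], b[2]))
        if z2 - z1 < 1e-12:
            shares[LAYERS.index(partition.layer_of_z(z1))] += leg
            continue
        for i, (lo, hi) in enumerate(bounds):
            overlap = min(z2, hi) - max(z1, lo)
            if overlap > 0:
                shares[i] += leg * overlap / (z2 - z1)
    return shares


def assign_layer(
    segment: VesselSegment | np.ndarray, partition: LayerPartition
) -> str:
    """Compartment holding the largest arclength share; ties go shallow."""
    poly = segment.polyline if isinstance(segment, VesselSegment) else segment
    shares = _layer_shares(poly, partition)
    tol = _TIE_RTOL * max(shares.sum(), 1.0)
    best = shares.max()
    for i, name in enumerate(LAYERS):
        if shares[i] >= best - tol:
            return name
    return LAYERS[int(np.argmax(shares))]  # pragma: no cover


# ---------------------------------------------------------------------------
# Per-layer metrics
# ---------------------------------------------------------------------------

def _resolve_area(network: VascularNetwork, roi_area_mm2: float | None) -> float:
    if roi_area_mm2 is None:
        if network.roi is None:
            raise ValidationError("roi_area_mm2 required (network has no ROI)")
        roi_area_mm2 = network.roi.roi_area_mm2
    if not roi_area_mm2 > 0:
        raise ValidationError("roi_area_mm2 must be > 0")
    return float(roi_area_mm2)


def segment_layers(
    network: VascularNetwork, partition: LayerPartition
) -> list[str]:
    return [assign_layer(seg, partition) for seg in network.segments]


def layer_metrics(
    network: VascularNetwork,
    partition: LayerPartition,
    roi_area_mm2: float | None = None,
) -> pd.DataFrame:
    """Vessel metrics per compartment and in total for one ROI.

    Per layer: vessel density (mm of vessel per mm^2 of field), segment
    density (count/mm^2), mean segment length (um) and mean tortuosity
    over segments with a defined chord.  The ``total`` row pools every
    segment regardless of layer, so per-layer densities sum to it exactly.
    """
    area = _resolve_area(network, roi_area_mm2)
    labels = segment_layers(network, partition)
    rows = []
    for name in LAYERS + ("total",):
        segs = (
            network.segments
            if name == "total"
            else [s for s, lab in zip(network.segments, labels) if lab == name]
        )
        lengths = np.array([s.arclength_um for s in segs])
        taus = np.array([s.tortuosity for s in segs])
        taus = taus[np.isfinite(taus)]
        rows.append(
            {
                "layer": name,
                "vessel_density_mm_per_mm2": lengths.sum() / 1000.0 / area,
                "segment_density_per_mm2": len(segs) / area,
                "mean_segment_length_um": lengths.mean() if len(segs) else np.nan,
                "mean_tortuosity": taus.mean() if len(taus) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("layer")


def pericyte_metrics(
    network: VascularNetwork,
    pericytes: list[PericyteAnnotation],
    partition: LayerPartition,
    roi_area_mm2: float | None = None,
    snap_tol_um: float = DEFAULT_SNAP_TOL_UM,
) -> tuple[pd.DataFrame, list[dict]]:
    """Pericyte density (count/mm^2) and coverage (um of vessel per
    pericyte) per compartment.

    Each soma is assigned the layer of the segment owning the nearest
    vessel point within ``snap_tol_um`` (exact distance ties resolved
    toward the shallower layer); a soma with no vessel within tolerance
    falls back to the compartment of its own depth, and is rejected with
    a QC entry if it also lies outside the partition range.  Coverage is
    the layer's total vessel arclength divided by its pericyte count,
    missing when the count is zero.
    """
    if not snap_tol_um > 0:
        raise ValidationError("snap_tol_um must be > 0")
    area = _resolve_area(network, roi_area_mm2)
    labels = segment_layers(network, partition)

    layer_len = {name: 0.0 for name in LAYERS}
    for seg, lab in zip(network.segments, labels):
        layer_len[lab] += seg.arclength_um

    points, owner = [], []
    for si, seg in enumerate(network.segments):
        for p in seg.polyline:
            points.append(p)
            owner.append(si)
    qc: list[dict] = []
    counts = {name: 0 for name in LAYERS}
    tree = cKDTree(np.asarray(points)) if points else None

    for soma in pericytes:
        pos = np.asarray(soma.position)
        layer = None
        if tree is not None:
            d, _ = tree.query(pos)
            if d <= snap_tol_um:
                near = tree.query_ball_point(pos, r=d * (1 + 1e-12) + 1e-9)
                cand = {labels[owner[i]] for i in near}
                layer = next(name for name in LAYERS if name in cand)
        if layer is None:
            z = pos[2]
            if partition.z_min <= z <= partition.z_max:
                layer = partition.layer_of_z(z)
            else:
                soma.assigned_layer = None
                qc.append(
                    {
                        "record": soma.soma_id,
                        "issue": "pericyte_rejected",
                        "detail": "no vessel within snap tolerance and depth "
                        "outside partition",
                    }
                )
                continue
        soma.assigned_layer = layer
        counts[layer] += 1

    rows = []
    for name in LAYERS:
        n = counts[name]
        rows.append(
            {
                "layer": name,
                "pericyte_density_per_mm2": n / area,
                "pericyte_coverage_um_per_pericyte": (
                    layer_len[name] / n if n else np.nan
                ),
            }
        )
    n_tot = sum(counts.values())
    rows.append(
        {
            "layer": "total",
            "pericyte_density_per_mm2": n_tot / area,
            "pericyte_coverage_um_per_pericyte": (
                sum(layer_len.values()) / n_tot if n_tot else np.nan
            ),
        }
    )
    return pd.DataFrame(rows).set_index("layer"), qc


def compute_metrics(
    network: VascularNetwork,
    pericytes: list[PericyteAnnotation],
    partition: LayerPartition,
    roi_area_mm2: float | None = None,
    snap_tol_um: float = DEFAULT_SNAP_TOL_UM,
) -> pd.DataFrame:
    """Full six-metric table (vessel + pericyte columns) for one ROI."""
    vm = layer_metrics(network, partition, roi_area_mm2)
    pm, qc = pericyte_metrics(network, pericytes, partition, roi_area_mm2,
                              snap_tol_um)
    network.qc_log.extend(qc)
    table = vm.join(pm).reset_index()
    table.insert(0, "roi_id", network.roi.roi_id if network.roi else "")
    return table


# ---------------------------------------------------------------------------
# Axial classification
# ---------------------------------------------------------------------------

@dataclass
class AxialClassCounts:
    """Counts and areal densities of the five axial-vessel classes."""

    counts: dict[str, int]
    densities: dict[str, float]
    n_chains: int = 0
    n_unclassified: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axial_class": list(AXIAL_CLASSES),
                "count": [self.counts[c] for c in AXIAL_CLASSES],
                "count_per_mm2": [self.densities[c] for c in AXIAL_CLASSES],
            }
        )


_CONTACT_CLASS = {
    frozenset({"S", "I"}): "SI_connecting",
    frozenset({"I", "D"}): "ID_connecting",
    frozenset({"S", "I", "D"}): "SID_connecting",
    frozenset({"S", "D"}): "SD_connecting",
}


def classify_axial(
    network: VascularNetwork,
    partition: LayerPartition,
    roi_area_mm2: float | None = None,
    interior_frac: float = DEFAULT_INTERIOR_FRAC,
) -> AxialClassCounts:
    """Classify inter-plexus axial chains and count gap bifurcations.

    Candidate axial segments carry at least ``interior_frac`` of their
    arclength inside the SI/ID gap compartments.  Candidates sharing a
    node whose depth lies outside every plexus slab are chained together
    (nodes inside a slab terminate chains).  A chain's plexus contact set
    is the set of slabs containing any of its polyline vertices, mapped to
    SI / ID / SID / SD connecting classes; chains with any other contact
    set are left unclassified.  Independently, every branch node (degree
    >= 3) whose depth lies inside the SI or ID compartment counts as one
    inter-plexus branching event.
    """
    area = _resolve_area(network, roi_area_mm2)
    counts = {c: 0 for c in AXIAL_CLASSES}

    candidates = []
    for si, seg in enumerate(network.segments):
        shares = _layer_shares(seg.polyline, partition)
        interior = shares[LAYERS.index("SI")] + shares[LAYERS.index("ID")]
        if interior >= interior_frac * seg.arclength_um * (1 - 1e-12):
            candidates.append(si)

    cand_set = set(candidates)
    idx_of = {si: k for k, si in enumerate(candidates)}
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    node_members: dict[str, list[int]] = {}
    for si in candidates:
        for nid in network.segments[si].end_nodes:
            node_members.setdefault(nid, []).append(si)
    for nid, members in node_members.items():
        zc = network.nodes[nid].position[2]
        if partition.slabs_containing(zc):
            continue  # a node inside a plexus slab terminates chains
        first = idx_of[members[0]]
        for other in members[1:]:
            ra, rb = find(first), find(idx_of[other])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    chains: dict[int, list[int]] = {}
    for si in candidates:
        chains.setdefault(find(idx_of[si]), []).append(si)

    n_unclassified = 0
    for members in chains.values():
        contact: set[str] = set()
        for si in members:
            for z in network.segments[si].polyline[:, 2]:
                contact |= partition.slabs_containing(float(z))
        cls = _CONTACT_CLASS.get(frozenset(contact))
        if cls is None:
            n_unclassified += 1
        else:
            counts[cls] += 1

    si_lo, si_hi = partition.layer_bounds["SI"]
    id_lo, id_hi = partition.layer_bounds["ID"]
    for node in network.branch_nodes():
        z = node.position[2]
        if si_lo <= z < si_hi or id_lo <= z < id_hi:
            counts["inter_plexus_branching"] += 1

    densities = {c: counts[c] / area for c in AXIAL_CLASSES}
    return AxialClassCounts(
        counts=counts,
        densities=densities,
        n_chains=len(chains),
        n_unclassified=n_unclassified,
    )
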