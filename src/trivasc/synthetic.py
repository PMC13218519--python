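"""Synthetic trilaminar vascular networks with exact ground truth.

The generator emulates the study conditions this package targets: 300 x
300 um retinal ROIs spanning a 95 um stack with three vascular plexuses
(superficial at ~5 um, intermediate at ~47.5 um, deep at ~90 um), axial
connectors between them, pericytes along the vessels, and two glycemia
groups of animals (13 euglycemic vs 14 hyperglycemic) sampled across four
eccentricity bands and ages 7-61 weeks.

Per plexus, a jittered square lattice is trimmed to a target total vessel
length; each edge becomes a sinusoidally perturbed polyline whose
amplitude is solved so the discretized arclength/chord ratio equals the
layer's tortuosity target exactly.  Axial connectors are built per class
by explicit geometry, so their plexus-contact sets — and hence the class
counts — are guaranteed by construction.

Every quantity the analysis pipeline later measures is recorded at
construction time in a :class:`GroundTruthLedger` using simple inline
summations, deliberately independent of the analysis modules, so the
ledger can serve as an oracle for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError
from .laminar import LAYERS, LayerPartition, partition_from_cuts
from .trace_io import (
    ECCENTRICITY_BANDS,
    PericyteAnnotation,
    RoiRecord,
    VesselPath,
)

__all__ = [
    "PlexusTargets",
    "SyntheticConfig",
    "GroundTruthLedger",
    "RoiSample",
    "generate_roi",
    "generate_cohort",
    "generate_bg_series",
    "PANEL_METRICS",
]


@dataclass
class PlexusTargets:
    """Per-plexus generation targets."""

    vessel_density_mm_per_mm2: float
    mean_segment_length_um: float
    tortuosity: float

    def __post_init__(self) -> None:
        if not self.vessel_density_mm_per_mm2 > 0:
            raise ValidationError("plexus vessel density must be > 0")
        if not self.mean_segment_length_um > 0:
            raise ValidationError("plexus segment length must be > 0")
        if not self.tortuosity >= 1.0:
            raise ValidationError("tortuosity target must be >= 1")


def _default_plexus_targets() -> dict[str, PlexusTargets]:
    # layer-wise euglycemic magnitudes: densities ~16/21/31 mm/mm^2,
    # segment lengths ~63/55/50 um, tortuosity ~1.1-1.2
    return {
        "S": PlexusTargets(15.81, 62.98, 1.11),
        "I": PlexusTargets(21.16, 55.28, 1.19),
        "D": PlexusTargets(30.73, 49.71, 1.17),
    }


def _default_coverage_targets() -> dict[str, float]:
    # um of vessel per pericyte, per compartment (euglycemic magnitudes)
    return {"S": 230.1, "SI": 130.6, "I": 105.6, "ID": 206.4, "D": 140.7}


def _default_axial_counts() -> dict[str, int]:
    # per-ROI counts matching ~49/76/66/14/12 per mm^2 at 0.09 mm^2
    return {"SI": 4, "ID": 7, "SID": 6, "SD": 1, "IPB": 1}


@dataclass
class SyntheticConfig:
    """Study-condition parameters for one synthetic ROI / cohort."""

    roi_size_um: tuple[float, float] = (300.0, 300.0)
    stack_depth_um: float = 95.0
    plexus_z_um: tuple[float, float, float] = (5.0, 47.5, 90.0)
    slab_halfwidth_um: float = 10.0
    plexus: dict[str, PlexusTargets] = field(default_factory=_default_plexus_targets)
    pericyte_coverage_um: dict[str, float] = field(
        default_factory=_default_coverage_targets
    )
    axial_counts: dict[str, int] = field(default_factory=_default_axial_counts)
    node_jitter_um: float = 4.0
    points_per_edge: int = 25
    connector_margin_um: float = 20.0
    connector_min_sep_um: float = 25.0
    n_per_group: tuple[int, int] = (13, 14)
    between_animal_cv: float = 0.10
    group_effect_cv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        zs, zi, zd = self.plexus_z_um
        if not (0 <= zs < zi < zd <= self.stack_depth_um):
            raise ValidationError(
                "plexus depths must be strictly increasing within the stack"
            )
        hw = self.slab_halfwidth_um
        if not (zs + hw < zi - hw and zi + hw < zd - hw):
            raise ValidationError("plexus slabs overlap; reduce slab half-width")
        for name, gap in (("SI", (zs, zi)), ("ID", (zi, zd))):
            frac = ((gap[1] - hw) - (gap[0] + hw)) / (gap[1] - gap[0])
            if frac < 0.5:
                raise ValidationError(
                    f"infeasible config: {name} connectors would carry only "
                    f"{frac:.0%} of their length inside the gap"
                )
        n_conn = sum(self.axial_counts.values())
        w, h = self.roi_size_um
        m, sep = self.connector_margin_um, self.connector_min_sep_um
        max_sites = (int((w - 2 * m) / sep) + 1) * (int((h - 2 * m) / sep) + 1)
        if n_conn > max_sites:
            raise ValidationError(
                f"infeasible config: {n_conn} axial connectors exceed the "
                f"{max_sites} available anchor sites"
            )

    @property
    def roi_area_mm2(self) -> float:
        return self.roi_size_um[0] * self.roi_size_um[1] / 1.0e6

    def partition(self) -> LayerPartition:
        """The explicit layer partition implied by the configured planes."""
        zs, zi, zd = self.plexus_z_um
        hw = self.slab_halfwidth_um
        zmax = self.stack_depth_um
        slabs = {
            "S": (max(0.0, zs - hw), zs + hw),
            "I": (zi - hw, zi + hw),
            "D": (zd - hw, min(zmax, zd + hw)),
        }
        return partition_from_cuts(
            (zs + hw, zi - hw, zi + hw, zd - hw), (0.0, zmax), slabs=slabs
        )


# ---------------------------------------------------------------------------
# Ground-truth ledger (independent inline bookkeeping)
# ---------------------------------------------------------------------------

def _inline_length(points: np.ndarray) -> float:
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        total += math.dist(a, b)
    return total


def _inline_layer(points: np.ndarray, cuts: list[float]) -> str:
    """Majority-arclength compartment, recomputed with plain loops.

    ``cuts`` are the four interior boundaries; the shallowest compartment
    wins exact ties.  Kept free of any laminar-module import so the
    ledger stays an independent oracle.
    """
    edges = [-math.inf] + list(cuts) + [math.inf]
    shares = [0.0] * 5
    for a, b in zip(points[:-1], points[1:]):
        leg = math.dist(a, b)
        z1, z2 = sorted((a[2], b[2]))
        if z2 - z1 < 1e-12:
            for i in range(5):
                if edges[i] <= z1 < edges[i + 1] or (i == 4 and z1 >= edges[4]):
                    shares[i] += leg
                    break
            continue
        for i in range(5):
            ov = min(z2, edges[i + 1]) - max(z1, edges[i])
            if ov > 0:
                shares[i] += leg * ov / (z2 - z1)
    best = max(shares)
    tol = 1e-9 * max(sum(shares), 1.0)
    for i, name in enumerate(LAYERS):
        if shares[i] >= best - tol:
            return name
    return LAYERS[shares.index(best)]


@dataclass
class GroundTruthLedger:
    """Exact per-ROI construction record, the parameter-recovery oracle."""

    roi_area_mm2: float
    layer_arclength_um: dict[str, float]
    layer_segment_count: dict[str, int]
    layer_tortuosities: dict[str, list[float]]
    pericyte_counts: dict[str, int]
    axial_counts: dict[str, int]

    def vessel_density(self, layer: str) -> float:
        return self.layer_arclength_um[layer] / 1000.0 / self.roi_area_mm2

    def segment_density(self, layer: str) -> float:
        return self.layer_segment_count[layer] / self.roi_area_mm2

    def mean_segment_length(self, layer: str) -> float:
        n = self.layer_segment_count[layer]
        return self.layer_arclength_um[layer] / n if n else float("nan")

    def mean_tortuosity(self, layer: str) -> float:
        taus = self.layer_tortuosities[layer]
        return sum(taus) / len(taus) if taus else float("nan")

    def pericyte_density(self, layer: str) -> float:
        return self.pericyte_counts[layer] / self.roi_area_mm2

    def pericyte_coverage(self, layer: str) -> float:
        n = self.pericyte_counts[layer]
        return self.layer_arclength_um[layer] / n if n else float("nan")

    def metrics_table(self) -> pd.DataFrame:
        """Ledger values shaped like the pipeline's per-layer metric table."""
        rows = []
        for name in LAYERS:
            rows.append(
                {
                    "layer": name,
                    "vessel_density_mm_per_mm2": self.vessel_density(name),
                    "segment_density_per_mm2": self.segment_density(name),
                    "mean_segment_length_um": self.mean_segment_length(name),
                    "mean_tortuosity": self.mean_tortuosity(name),
                    "pericyte_density_per_mm2": self.pericyte_density(name),
                    "pericyte_coverage_um_per_pericyte": self.pericyte_coverage(
                        name
                    ),
                }
            )
        total_len = sum(self.layer_arclength_um.values())
        total_n = sum(self.layer_segment_count.values())
        all_taus = [t for ts in self.layer_tortuosities.values() for t in ts]
        total_pc = sum(self.pericyte_counts.values())
        rows.append(
            {
                "layer": "total",
                "vessel_density_mm_per_mm2": total_len / 1000.0 / self.roi_area_mm2,
                "segment_density_per_mm2": total_n / self.roi_area_mm2,
                "mean_segment_length_um": (
                    total_len / total_n if total_n else float("nan")
                ),
                "mean_tortuosity": (
                    sum(all_taus) / len(all_taus) if all_taus else float("nan")
                ),
                "pericyte_density_per_mm2": total_pc / self.roi_area_mm2,
                "pericyte_coverage_um_per_pericyte": (
                    total_len / total_pc if total_pc else float("nan")
                ),
            }
        )
        return pd.DataFrame(rows).set_index("layer")


@dataclass
class RoiSample:
    paths: list[VesselPath]
    pericytes: list[PericyteAnnotation]
    roi: RoiRecord
    ledger: GroundTruthLedger


# ---------------------------------------------------------------------------
# Geometry builders
# ---------------------------------------------------------------------------

def _sinusoid_polyline(
    a_xy: np.ndarray, b_xy: np.ndarray, z: float, tau: float, n_points: int
) -> np.ndarray:
    """In-plane polyline from A to B whose discretized arclength/chord
    ratio equals ``tau`` exactly (amplitude solved numerically)."""
    d = b_xy - a_xy
    c = float(np.hypot(*d))
    perp = np.array([-d[1], d[0]]) / c
    t = np.linspace(0.0, 1.0, n_points)
    base = a_xy[None, :] + t[:, None] * d[None, :]

    def ratio(amp: float) -> float:
        xy = base + (amp * np.sin(2.0 * np.pi * t))[:, None] * perp[None, :]
        return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1))) / c

    if tau <= 1.0 + 1e-12:
        amp = 0.0
    else:
        amp = brentq(lambda a: ratio(a) - tau, 0.0, 2.0 * c, xtol=1e-12)
    xy = base + (amp * np.sin(2.0 * np.pi * t))[:, None] * perp[None, :]
    return np.column_stack([xy, np.full(n_points, z)])


def _plexus_paths(
    config: SyntheticConfig, name: str, z: float, rng: np.random.Generator,
    density_scale: float,
) -> list[np.ndarray]:
    """Jittered-lattice plexus trimmed to the target total length."""
    tgt = config.plexus[name]
    w, h = config.roi_size_um
    target_len = (
        tgt.vessel_density_mm_per_mm2 * density_scale * config.roi_area_mm2 * 1000.0
    )
    spacing = tgt.mean_segment_length_um / tgt.tortuosity
    nx = max(2, int(w / spacing) + 1)
    ny = max(2, int(h / spacing) + 1)
    x0 = (w - (nx - 1) * spacing) / 2.0
    y0 = (h - (ny - 1) * spacing) / 2.0
    jit = config.node_jitter_um
    nodes = np.empty((nx, ny, 2))
    for i in range(nx):
        for j in range(ny):
            nodes[i, j] = (
                x0 + i * spacing + rng.uniform(-jit, jit),
                y0 + j * spacing + rng.uniform(-jit, jit),
            )
    edges = [((i, j), (i + 1, j)) for i in range(nx - 1) for j in range(ny)]
    edges += [((i, j), (i, j + 1)) for i in range(nx) for j in range(ny - 1)]
    order = rng.permutation(len(edges))

    polylines: list[np.ndarray] = []
    total = 0.0
    for k in order:
        (ia, ja), (ib, jb) = edges[k]
        poly = _sinusoid_polyline(
            nodes[ia, ja], nodes[ib, jb], z, tgt.tortuosity,
            config.points_per_edge,
        )
        length = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
        if total + length > target_len:
            # keep the edge only if it lands closer to the target
            if (total + length - target_len) < (target_len - total):
                polylines.append(poly)
                total += length
            break
        polylines.append(poly)
        total += length
    return polylines


def _connector_sites(
    config: SyntheticConfig, n: int, avoid: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random in-plane anchor sites, separated from each other and from
    lattice nodes."""
    w, h = config.roi_size_um
    m = config.connector_margin_um
    sites: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(2000):
            p = rng.uniform([m, m], [w - m, h - m])
            if sites and min(np.linalg.norm(p - s) for s in sites) < (
                config.connector_min_sep_um
            ):
                continue
            if avoid.size and np.min(np.linalg.norm(avoid - p, axis=1)) < 3.0:
                continue
            sites.append(p)
            break
        else:  # pragma: no cover - guarded by config feasibility check
            raise ValidationError("could not place axial connector sites")
    return sites


def _connector_polylines(
    config: SyntheticConfig, sites: list[np.ndarray]
) -> list[tuple[str, np.ndarray]]:
    """Axial connector polylines per class, contact sets by construction."""
    zs, zi, zd = config.plexus_z_um
    hw = config.slab_halfwidth_um
    out: list[tuple[str, np.ndarray]] = []
    it = iter(sites)

    for _ in range(config.axial_counts.get("SI", 0)):
        x, y = next(it)
        z = np.linspace(zs, zi, 9)
        out.append(("SI", np.column_stack([np.full(9, x), np.full(9, y), z])))
    for _ in range(config.axial_counts.get("ID", 0)):
        x, y = next(it)
        z = np.linspace(zi, zd, 9)
        out.append(("ID", np.column_stack([np.full(9, x), np.full(9, y), z])))
    for _ in range(config.axial_counts.get("SID", 0)):
        x, y = next(it)
        z = np.unique(np.concatenate([np.linspace(zs, zd, 17), [zi]]))
        n = z.size
        out.append(("SID", np.column_stack([np.full(n, x), np.full(n, y), z])))
    for _ in range(config.axial_counts.get("SD", 0)):
        x, y = next(it)
        # detour whose sampled vertices skip the intermediate slab
        pts = np.array(
            [
                [x, y, zs],
                [x, y, zi - hw - 2.5],
                [x + 15.0, y, zi + hw + 2.5],
                [x, y, zd],
            ]
        )
        out.append(("SD", pts))
    for _ in range(config.axial_counts.get("IPB", 0)):
        x, y = next(it)
        zc = (zs + hw + zi - hw) / 2.0  # middle of the SI gap
        center = np.array([x, y, zc])
        for arm in (
            np.array([8.0, 0.0, -4.0]),
            np.array([-6.0, 6.0, 4.0]),
            np.array([0.0, -8.0, 3.0]),
        ):
            out.append(("IPB", np.vstack([center, center + arm])))
    return out


# ---------------------------------------------------------------------------
# ROI generation
# ---------------------------------------------------------------------------

def generate_roi(
    config: SyntheticConfig,
    rng: np.random.Generator | int,
    roi: RoiRecord | None = None,
    density_scale: float = 1.0,
    coverage_scale: float = 1.0,
) -> RoiSample:
    """Generate one synthetic ROI with its exact ground-truth ledger.

    ``density_scale`` multiplies every plexus length target and
    ``coverage_scale`` the pericyte spacing targets, which is how cohort
    generation realizes animal- and group-level effects geometrically.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if roi is None:
        roi = RoiRecord("roi", roi_area_mm2=config.roi_area_mm2)

    zs, zi, zd = config.plexus_z_um
    hw = config.slab_halfwidth_um
    cuts = [zs + hw, zi - hw, zi + hw, zd - hw]

    layered: list[tuple[str, np.ndarray]] = []
    lattice_nodes = []
    for name, z in zip(("S", "I", "D"), config.plexus_z_um):
        polys = _plexus_paths(config, name, z, rng, density_scale)
        for poly in polys:
            layered.append((name, poly))
            lattice_nodes.append(poly[0, :2])
            lattice_nodes.append(poly[-1, :2])

    n_conn_sites = sum(config.axial_counts.values())
    avoid = np.asarray(lattice_nodes) if lattice_nodes else np.empty((0, 2))
    sites = _connector_sites(config, n_conn_sites, avoid, rng)
    connectors = _connector_polylines(config, sites)
    # sanity: every connector must really be a majority-gap (axial) vessel
    for cls, poly in connectors:
        if cls == "IPB":
            continue
        shares_layer = _inline_layer(poly, cuts)
        if shares_layer not in ("SI", "ID", "I"):
            raise ValidationError(  # pragma: no cover
                f"infeasible config: {cls} connector assigned to {shares_layer}"
            )
    layered.extend((_inline_layer(poly, cuts), poly) for _, poly in connectors)

    # ledger bookkeeping with plain summations
    layer_len = {name: 0.0 for name in LAYERS}
    layer_count = {name: 0 for name in LAYERS}
    layer_taus: dict[str, list[float]] = {name: [] for name in LAYERS}
    paths: list[VesselPath] = []
    for layer, poly in layered:
        length = _inline_length(poly)
        ch = math.dist(poly[0], poly[-1])
        layer_len[layer] += length
        layer_count[layer] += 1
        if ch > 1.0:
            layer_taus[layer].append(length / ch)
        paths.append(VesselPath(f"p{len(paths) + 1}", poly))

    # pericytes: spacing chosen to hit the per-layer coverage target
    pericytes: list[PericyteAnnotation] = []
    pc_counts = {name: 0 for name in LAYERS}
    for name in LAYERS:
        cov = config.pericyte_coverage_um[name] * coverage_scale
        n = int(round(layer_len[name] / cov)) if layer_len[name] > 0 else 0
        if n == 0:
            continue
        candidates = [
            tuple(pt)
            for layer, poly in layered
            if layer == name
            for pt in poly[1:-1]
        ]
        if n > len(candidates):
            n = len(candidates)
        idx = rng.choice(len(candidates), size=n, replace=False)
        for i in sorted(idx):
            pericytes.append(
                PericyteAnnotation(f"pc{len(pericytes) + 1}", candidates[i])
            )
        pc_counts[name] = n

    axial = {
        "SI_connecting": config.axial_counts.get("SI", 0),
        "ID_connecting": config.axial_counts.get("ID", 0),
        "SID_connecting": config.axial_counts.get("SID", 0),
        "SD_connecting": config.axial_counts.get("SD", 0),
        "inter_plexus_branching": config.axial_counts.get("IPB", 0),
    }
    ledger = GroundTruthLedger(
        roi_area_mm2=roi.roi_area_mm2,
        layer_arclength_um=layer_len,
        layer_segment_count=layer_count,
        layer_tortuosities=layer_taus,
        pericyte_counts=pc_counts,
        axial_counts=axial,
    )
    return RoiSample(paths=paths, pericytes=pericytes, roi=roi, ledger=ledger)


# ---------------------------------------------------------------------------
# Cohorts and blood glucose
# ---------------------------------------------------------------------------

#: Whole-retina metric panel: name -> (euglycemic mean, between-animal SD).
PANEL_METRICS = {
    "vessel_density_mm_per_mm2": (80.92, 12.44),
    "segment_density_per_mm2": (1548.0, 362.8),
    "mean_segment_length_um": (53.75, 4.63),
    "mean_tortuosity": (1.30, 0.07),
    "pericyte_density_per_mm2": (634.9, 116.4),
    "pericyte_coverage_um_per_pericyte": (129.5, 14.89),
}

#: Weekly blood-glucose model: euglycemic N(152.9, 10.0) mg/dL; after
#: hyperglycemia onset at week 4, N(491.6, 62.58) capped at the 600 mg/dL
#: meter ceiling.
BG_EUGLYCEMIC = (152.9, 10.0)
BG_HYPERGLYCEMIC = (491.6, 62.58)
BG_CEILING = 600.0
BG_ONSET_WEEK = 4


def generate_bg_series(
    group: str, age_weeks: int, rng: np.random.Generator
) -> np.ndarray:
    """Weekly blood glucose for one animal from week 1 to ``age_weeks``."""
    weeks = np.arange(1, age_weeks + 1)
    eu = rng.normal(*BG_EUGLYCEMIC, size=weeks.size)
    if group == "euglycemic":
        return eu
    hyper = np.minimum(rng.normal(*BG_HYPERGLYCEMIC, size=weeks.size), BG_CEILING)
    return np.where(weeks < BG_ONSET_WEEK, eu, hyper)


def generate_cohort(
    config: SyntheticConfig,
    seed: int | np.random.Generator = 0,
    geometry: str = "panel",
    rois_per_animal: int = 4,
    group_effect: dict[str, float] | None = None,
) -> dict:
    """Generate a two-group animal cohort with metric panel and BG series.

    ``geometry="panel"`` draws per-animal metric values directly
    (group mean + normal between-animal effect) — fast, for statistical
    plumbing and calibration.  ``geometry="full"`` realizes each animal
    through per-ROI geometric generation across the eccentricity bands
    (density and coverage targets scaled by the animal effect) and reads
    the panel off the ground-truth ledgers.

    ``group_effect`` maps metric names to additive shifts (panel mode) of
    the hyperglycemic group mean, or a single ``"scale"`` entry to a
    multiplicative density shift (full mode).  Returns a dict with keys
    ``panel`` (tidy per-stack DataFrame), ``bg`` (animal -> weekly
    series) and, in full mode, ``samples`` (animal -> list of RoiSample).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_e, n_h = config.n_per_group
    if min(n_e, n_h) < 2:
        raise ValidationError("cohort needs >= 2 animals per group")
    group_effect = group_effect or {}

    rows = []
    bg: dict[str, np.ndarray] = {}
    samples: dict[str, list[RoiSample]] = {}
    animals = [("euglycemic", f"E{i + 1}") for i in range(n_e)]
    animals += [("hyperglycemic", f"H{i + 1}") for i in range(n_h)]

    for group, animal in animals:
        age = int(rng.integers(7, 62))
        bg[animal] = generate_bg_series(group, age, rng)
        if geometry == "panel":
            effects = {
                m: rng.normal(0.0, sd) for m, (_, sd) in PANEL_METRICS.items()
            }
            for band in ECCENTRICITY_BANDS[:rois_per_animal]:
                for m, (mean, _) in PANEL_METRICS.items():
                    shift = (
                        group_effect.get(m, 0.0)
                        if group == "hyperglycemic"
                        else 0.0
                    )
                    rows.append(
                        {
                            "animal_id": animal,
                            "glycemia_group": group,
                            "age_weeks": age,
                            "eccentricity_mm": band,
                            "metric": m,
                            "value": mean + shift + effects[m],
                        }
                    )
        elif geometry == "full":
            scale = 1.0 + rng.normal(0.0, config.between_animal_cv)
            if group == "hyperglycemic":
                scale *= 1.0 + group_effect.get("scale", 0.0)
            scale = max(scale, 0.2)
            samples[animal] = []
            for k in range(rois_per_animal):
                band = ECCENTRICITY_BANDS[k % len(ECCENTRICITY_BANDS)]
                roi = RoiRecord(
                    f"{animal}_roi{k + 1}",
                    animal_id=animal,
                    glycemia_group=group,
                    age_weeks=age,
                    eccentricity_mm=band,
                    roi_area_mm2=config.roi_area_mm2,
                )
                sample = generate_roi(config, rng, roi=roi, density_scale=scale)
                samples[animal].append(sample)
                table = sample.ledger.metrics_table()
                for m in PANEL_METRICS:
                    rows.append(
                        {
                            "animal_id": animal,
                            "glycemia_group": group,
                            "age_weeks": age,
                            "eccentricity_mm": band,
                            "metric": m,
                            "value": float(table.loc["total", m]),
                        }
                    )
        else:
            raise ValidationError(f"unknown geometry mode {geometry!r}")

    out = {"panel": pd.DataFrame(rows), "bg": bg}
    if geometry == "full":
        out["samples"] = samples
    return out
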