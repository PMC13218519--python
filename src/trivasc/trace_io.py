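"""Readers and writers for vessel traces, pericyte annotations and metrics.

Traced centerlines travel as SWC (the standard neurite/vessel skeleton
interchange format, 7 whitespace-separated columns) or as a flat CSV path
table (``path_id, point_index, x_um, y_um, z_um``) matching the coordinate
export produced by manual tracing tools.  Pericyte somata are point tables,
ROI metadata is JSON, and metric tables round-trip through CSV.

All coordinates are micrometres.  The z axis increases from the superficial
(vitreal) side toward the deep (scleral) side of the retina.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, StructureError, ValidationError

__all__ = [
    "VesselPath",
    "PericyteAnnotation",
    "RoiRecord",
    "ECCENTRICITY_BANDS",
    "read_swc",
    "write_swc",
    "read_path_table",
    "write_path_table",
    "read_pericytes",
    "write_pericytes",
    "write_metrics",
    "read_metrics",
    "read_roi_record",
    "write_roi_record",
]

#: The four radial sampling bands, in mm from the optic disc.
ECCENTRICITY_BANDS = ("0-0.5", "0.5-1.0", "1.0-1.5", "1.5-2.0")

#: Nominal area of a 300 x 300 um imaging field, in mm^2.
DEFAULT_ROI_AREA_MM2 = 0.09


@dataclass
class VesselPath:
    """One traced centerline: an ordered run of 3D points in micrometres.

    A path is the atomic tracing record — by convention each vessel
    segment (the stretch between two branch points or endpoints) is
    traced as its own path.
    """

    path_id: str
    points: np.ndarray  # (n, 3) float array, n >= 2
    radius: np.ndarray | None = None  # optional per-point radius, um

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(
                f"path {self.path_id!r}: points must be an (n, 3) array"
            )
        if pts.shape[0] < 2:
            raise ValidationError(f"path {self.path_id!r}: needs >= 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"path {self.path_id!r}: non-finite coordinate")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= 0.0):
            raise ValidationError(
                f"path {self.path_id!r}: consecutive points must be distinct"
            )
        self.points = pts
        if self.radius is not None:
            r = np.asarray(self.radius, dtype=float)
            if r.shape != (pts.shape[0],):
                raise ValidationError(
                    f"path {self.path_id!r}: radius length must match points"
                )
            self.radius = r

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class PericyteAnnotation:
    """A pericyte soma location; ``assigned_layer`` is filled by analysis."""

    soma_id: str
    position: tuple[float, float, float]
    assigned_layer: str | None = None

    def __post_init__(self) -> None:
        pos = tuple(float(v) for v in self.position)
        if len(pos) != 3 or not all(np.isfinite(pos)):
            raise ValidationError(f"soma {self.soma_id!r}: invalid position")
        self.position = pos


@dataclass
class RoiRecord:
    """Metadata for one 300 x 300 um region of interest."""

    roi_id: str
    animal_id: str = ""
    glycemia_group: str = "euglycemic"
    age_weeks: float = 0.0
    eccentricity_mm: str = ECCENTRICITY_BANDS[0]
    roi_area_mm2: float = DEFAULT_ROI_AREA_MM2

    def __post_init__(self) -> None:
        if self.glycemia_group not in ("euglycemic", "hyperglycemic"):
            raise ValidationError(
                f"glycemia_group must be euglycemic|hyperglycemic, "
                f"got {self.glycemia_group!r}"
            )
        if self.eccentricity_mm not in ECCENTRICITY_BANDS:
            raise ValidationError(
                f"eccentricity_mm must be one of {ECCENTRICITY_BANDS}, "
                f"got {self.eccentricity_mm!r}"
            )
        if not self.roi_area_mm2 > 0:
            raise ValidationError("roi_area_mm2 must be > 0")


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(stream: IO[str], unit_scale: float = 1.0) -> list[VesselPath]:
    """Read an SWC file and split it into unbranched centerline paths.

    Every maximal unbranched chain between structure points of degree != 2
    becomes one :class:`VesselPath`; a branch point is therefore shared by
    all chains meeting there.  Coordinates are multiplied by ``unit_scale``
    (micrometres per SWC coordinate unit).  Record order is irrelevant:
    parent pointers are resolved after the whole file is read.
    """
    samples: dict[int, tuple[float, float, float, float, int]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise ParseError(
                f"SWC line {lineno}: expected 7 columns, got {len(cols)}"
            )
        try:
            sid = int(cols[0])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as exc:
            raise ParseError(f"SWC line {lineno}: {exc}") from None
        if sid in samples:
            raise StructureError(f"SWC line {lineno}: duplicate sample id {sid}")
        samples[sid] = (x * unit_scale, y * unit_scale, z * unit_scale,
                        r * unit_scale, parent)

    if len(samples) < 2:
        raise StructureError("SWC input has fewer than 2 samples")

    adjacency: dict[int, list[int]] = {sid: [] for sid in samples}
    for sid, (_, _, _, _, parent) in samples.items():
        if parent == -1:
            continue
        if parent not in samples:
            raise StructureError(f"SWC sample {sid}: dangling parent id {parent}")
        adjacency[sid].append(parent)
        adjacency[parent].append(sid)

    degree = {sid: len(nbrs) for sid, nbrs in adjacency.items()}
    break_nodes = sorted(sid for sid, d in degree.items() if d != 2)

    paths: list[VesselPath] = []
    visited_edges: set[frozenset[int]] = set()

    def _emit(chain: list[int]) -> None:
        pts = np.array([samples[s][:3] for s in chain], dtype=float)
        rad = np.array([samples[s][3] for s in chain], dtype=float)
        paths.append(VesselPath(f"p{len(paths) + 1}", pts, radius=rad))

    def _walk(start: int, nxt: int) -> None:
        chain = [start]
        prev, cur = start, nxt
        while True:
            edge = frozenset((prev, cur))
            if edge in visited_edges:
                return
            visited_edges.add(edge)
            chain.append(cur)
            if degree[cur] != 2:
                break
            nbrs = [n for n in adjacency[cur] if n != prev]
            prev, cur = cur, nbrs[0]
        _emit(chain)

    for start in break_nodes:
        for nbr in sorted(adjacency[start]):
            _walk(start, nbr)

    # cycles made entirely of degree-2 samples have no break node
    for sid in sorted(samples):
        for nbr in sorted(adjacency[sid]):
            if frozenset((sid, nbr)) not in visited_edges:
                _walk(sid, nbr)

    return paths


def write_swc(paths: Iterable[VesselPath], stream: IO[str]) -> None:
    """Write paths as SWC, one rooted chain per path (type code 7)."""
    stream.write("# id type x y z radius parent\n")
    next_id = 1
    for path in paths:
        radii = path.radius if path.radius is not None else np.ones(path.n_points)
        parent = -1
        for (x, y, z), r in zip(path.points, radii):
            stream.write(f"{next_id} 7 {x:.6f} {y:.6f} {z:.6f} {r:.6f} {parent}\n")
            parent = next_id
            next_id += 1


# ---------------------------------------------------------------------------
# Path table
# ---------------------------------------------------------------------------

_PATH_COLUMNS = ["path_id", "point_index", "x_um", "y_um", "z_um"]


def read_path_table(stream: IO[str]) -> list[VesselPath]:
    """Read a CSV path table; rows grouped by path id, ordered by index."""
    df = pd.read_csv(stream, dtype={"path_id": str})
    missing = [c for c in _PATH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"path table missing columns: {missing}")
    for col in ("x_um", "y_um", "z_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            raise ParseError(
                f"path table row {bad[0] + 2}: non-numeric value in {col!r}"
            )
        df[col] = coerced
    if df.duplicated(subset=["path_id", "point_index"]).any():
        dup = df[df.duplicated(subset=["path_id", "point_index"])].iloc[0]
        raise StructureError(
            f"duplicate (path_id, point_index): ({dup['path_id']}, "
            f"{int(dup['point_index'])})"
        )
    paths = []
    for pid, grp in df.groupby("path_id", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        paths.append(VesselPath(str(pid), pts))
    return paths


def write_path_table(paths: Iterable[VesselPath], stream: IO[str]) -> None:
    rows = []
    for path in paths:
        for i, (x, y, z) in enumerate(path.points):
            rows.append((path.path_id, i, x, y, z))
    pd.DataFrame(rows, columns=_PATH_COLUMNS).to_csv(stream, index=False)


# ---------------------------------------------------------------------------
# Pericytes
# ---------------------------------------------------------------------------

def read_pericytes(stream: IO[str]) -> list[PericyteAnnotation]:
    """Read a pericyte soma table (``soma_id, x_um, y_um, z_um``).

    An empty table (header only) is valid: an ROI may simply contain no
    annotated somata.
    """
    df = pd.read_csv(stream, dtype={"soma_id": str})
    required = ["soma_id", "x_um", "y_um", "z_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"pericyte table missing columns: {missing}")
    if df.empty:
        return []
    if df["soma_id"].duplicated().any():
        dup = df["soma_id"][df["soma_id"].duplicated()].iloc[0]
        raise StructureError(f"duplicate soma_id: {dup!r}")
    out = []
    for _, row in df.iterrows():
        vals = [row["x_um"], row["y_um"], row["z_um"]]
        if any(pd.isna(pd.to_numeric(v, errors="coerce")) for v in vals):
            raise ParseError(
                f"soma {row['soma_id']!r}: missing or non-numeric coordinate"
            )
        out.append(
            PericyteAnnotation(str(row["soma_id"]), tuple(float(v) for v in vals))
        )
    return out


def write_pericytes(somata: Iterable[PericyteAnnotation], stream: IO[str]) -> None:
    rows = [(s.soma_id, *s.position) for s in somata]
    pd.DataFrame(rows, columns=["soma_id", "x_um", "y_um", "z_um"]).to_csv(
        stream, index=False
    )


# ---------------------------------------------------------------------------
# Metrics tables and ROI metadata
# ---------------------------------------------------------------------------

METRIC_COLUMNS = [
    "roi_id",
    "layer",
    "vessel_density_mm_per_mm2",
    "segment_density_per_mm2",
    "mean_segment_length_um",
    "mean_tortuosity",
    "pericyte_density_per_mm2",
    "pericyte_coverage_um_per_pericyte",
]


def write_metrics(table: pd.DataFrame, stream: IO[str]) -> None:
    """Write a metrics table with a stable column order (CSV)."""
    cols = [c for c in METRIC_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(stream, index=False)


def read_metrics(stream: IO[str]) -> pd.DataFrame:
    return pd.read_csv(stream, dtype={"roi_id": str, "layer": str})


def write_roi_record(roi: RoiRecord, stream: IO[str]) -> None:
    json.dump(
        {
            "roi_id": roi.roi_id,
            "animal_id": roi.animal_id,
            "glycemia_group": roi.glycemia_group,
            "age_weeks": roi.age_weeks,
            "eccentricity_mm": roi.eccentricity_mm,
            "roi_area_mm2": roi.roi_area_mm2,
        },
        stream,
        indent=2,
    )


def read_roi_record(stream: IO[str]) -> RoiRecord:
    data = json.load(stream)
    known = {
        "roi_id", "animal_id", "glycemia_group", "age_weeks",
        "eccentricity_mm", "roi_area_mm2",
    }
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown ROI metadata keys: {sorted(unknown)}")
    return RoiRecord(**data)
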