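"""Point-pattern morphometrics of annotated presynaptic terminals.

An annotation (nm coordinates, arbitrary origin) holds the terminal plasma
membrane as a closed simple polygon, the marked centers of synaptic vesicles
and/or immunogold particles, and the active zone as a contiguous polyline
along the membrane.  Derived metrics: polygon area (shoelace, via shapely),
maximum Feret diameter (max pairwise distance over convex-hull vertices),
active-zone length, point density (boundary points counted inside), and the
perpendicular-distance profile of points to the active zone, normalized by
active-zone length, keeping only points whose orthogonal foot lands on an
active-zone segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

__all__ = [
    "TerminalAnnotation",
    "TerminalMetrics",
    "read_annotation",
    "write_annotation",
    "polygon_area",
    "max_feret",
    "polyline_length",
    "point_density",
    "az_distance_profile",
    "compare_profiles",
    "terminal_metrics",
]

NM2_PER_UM2 = 1e6


@dataclass
class TerminalAnnotation:
    """Membrane polygon, marked points, and active-zone polyline (all in nm)."""

    membrane: np.ndarray            # (n, 2), closed implicitly
    points: np.ndarray              # (m, 2)
    kinds: np.ndarray               # (m,), "vesicle" | "gold"
    active_zone: np.ndarray         # (k, 2), contiguous membrane sub-polyline
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membrane = np.asarray(self.membrane, dtype=float)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.active_zone = np.asarray(self.active_zone, dtype=float)
        if self.membrane.shape[0] < 3:
            raise ValueError("membrane polygon needs >= 3 vertices")

    def points_of(self, kind: str) -> np.ndarray:
        return self.points[self.kinds == kind]


@dataclass
class TerminalMetrics:
    area_um2: float
    max_feret_nm: float
    az_length_nm: float
    vesicle_density_per_um2: float
    gold_density_per_um2: float
    az_distances: pd.DataFrame  # distance_nm, normalized, included, kind


def write_annotation(ann: TerminalAnnotation, path) -> None:
    payload = {
        "membrane": ann.membrane.tolist(),
        "active_zone": ann.active_zone.tolist(),
        "points": [
            {"x": float(x), "y": float(y), "kind": str(k)}
            for (x, y), k in zip(ann.points, ann.kinds)
        ],
        "units": "nm",
    }
    Path(path).write_text(json.dumps(payload))


def read_annotation(path) -> TerminalAnnotation:
    payload = json.loads(Path(path).read_text())
    pts = payload.get("points", [])
    return TerminalAnnotation(
        membrane=np.asarray(payload["membrane"], dtype=float),
        points=np.asarray([[p["x"], p["y"]] for p in pts], dtype=float).reshape(-1, 2),
        kinds=np.asarray([p["kind"] for p in pts], dtype=object),
        active_zone=np.asarray(payload["active_zone"], dtype=float),
    )


def _polygon(membrane: np.ndarray) -> Polygon:
    poly = Polygon(np.asarray(membrane, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise ValueError("membrane polygon is degenerate or self-intersecting")
    return poly


def polygon_area(membrane: np.ndarray) -> float:
    """Shoelace area of the membrane polygon in um^2 (orientation-independent)."""
    return _polygon(membrane).area / NM2_PER_UM2


def max_feret(membrane: np.ndarray) -> float:
    """Maximum Feret (caliper) diameter in nm.

    The maximum pairwise vertex distance is attained on the convex hull, so
    only hull vertices are paired; non-convex membranes are supported.
    """
    pts = np.asarray(membrane, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 vertices")
    try:
        hull = pts[ConvexHull(pts).vertices]
    except Exception as exc:  # collinear/degenerate input
        raise ValueError("degenerate polygon") from exc
    d = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def polyline_length(polyline: np.ndarray) -> float:
    polyline = np.asarray(polyline, dtype=float)
    if polyline.shape[0] < 2:
        raise ValueError("polyline needs >= 2 vertices")
    return float(np.sqrt((np.diff(polyline, axis=0) ** 2).sum(1)).sum())


def point_density(points: np.ndarray, membrane: np.ndarray) -> float:
    """Points per um^2 inside the membrane; boundary points count as inside."""
    poly = _polygon(membrane)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.shape[0] == 0:
        return 0.0
    inside = sum(poly.covers(Point(p)) for p in points)
    return inside / (poly.area / NM2_PER_UM2)


def az_distance_profile(
    points: np.ndarray,
    active_zone: np.ndarray,
    az_length: float | None = None,
) -> pd.DataFrame:
    """Perpendicular distances from points to the active-zone polyline.

    For each point, the minimum perpendicular distance over all active-zone
    segments whose orthogonal foot lies within the segment; points with no
    valid foot on any segment are excluded (``included`` False, distance
    NaN).  ``normalized`` = distance / active-zone length.  All distances
    are non-negative magnitudes.
    """
    az = np.asarray(active_zone, dtype=float)
    if az.shape[0] < 2:
        raise ValueError("active zone needs >= 2 vertices")
    L = polyline_length(az) if az_length is None else float(az_length)
    if L <= 0:
        raise ValueError("zero-length active zone")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    a, b = az[:-1], az[1:]
    seg = b - a                                  # (S, 2)
    seg_len2 = (seg ** 2).sum(1)
    valid_seg = seg_len2 > 0

    rows = []
    for p in pts:
        ap = p - a                               # (S, 2)
        t = np.where(valid_seg, (ap * seg).sum(1) / np.where(valid_seg, seg_len2, 1.0), -1.0)
        on = valid_seg & (t >= 0.0) & (t <= 1.0)
        if not on.any():
            rows.append((float("nan"), float("nan"), False))
            continue
        foot = a[on] + t[on, None] * seg[on]
        dist = float(np.sqrt(((p - foot) ** 2).sum(1)).min())
        rows.append((dist, dist / L, True))
    return pd.DataFrame(rows, columns=["distance_nm", "normalized", "included"])


def compare_profiles(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of distance (or density) samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def terminal_metrics(ann: TerminalAnnotation) -> TerminalMetrics:
    """All scalar morphometrics plus the per-point AZ distance table."""
    area = polygon_area(ann.membrane)
    az_len = polyline_length(ann.active_zone)
    profiles = []
    for kind in ("vesicle", "gold"):
        pts = ann.points_of(kind)
        if pts.size:
            df = az_distance_profile(pts, ann.active_zone, az_len)
            df["kind"] = kind
            profiles.append(df)
    az_df = (
        pd.concat(profiles, ignore_index=True)
        if profiles
        else pd.DataFrame(columns=["distance_nm", "normalized", "included", "kind"])
    )
    return TerminalMetrics(
        area_um2=area,
        max_feret_nm=max_feret(ann.membrane),
        az_length_nm=az_len,
        vesicle_density_per_um2=point_density(ann.points_of("vesicle"), ann.membrane),
        gold_density_per_um2=point_density(ann.points_of("gold"), ann.membrane),
        az_distances=az_df,
    )
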