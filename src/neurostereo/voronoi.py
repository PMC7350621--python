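"""Voronoi tessellation of neuron positions and spatial-pattern classification.

Each generator point (a neuron soma profile) gets the polygon of locations
closer to it than to any other point; the polygon area measures the space a
cell occupies.  The coefficient of variation of polygon areas,
CV = sd / mean × 100, is scale-free and classifies the arrangement:

    CV < 33%        regular
    33% ≤ CV ≤ 64%  random (complete spatial randomness gives ≈ 53%)
    CV > 64%        clustered

Two edge policies are offered.  ``exclude_boundary`` (default) drops
polygons that are unbounded or touch the window edge, whose truncated areas
would inflate the CV; ``clip_to_window`` intersects every polygon with the
window, so the retained areas partition the window exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import voronoi_diagram

from .geometry import PointPattern2D

REGULAR_MAX_CV = 33.0
RANDOM_MAX_CV = 64.0


@dataclass
class VoronoiSummary:
    """Polygon-area statistics and the pattern classification."""

    polygon_areas: np.ndarray
    mean_area: float
    cv: float          # percent
    classification: str

    @property
    def n_polygons(self) -> int:
        return len(self.polygon_areas)


def _region_polygon(vor: Voronoi, point_index: int) -> Polygon | None:
    region = vor.regions[vor.point_region[point_index]]
    if not region or -1 in region:
        return None
    verts = vor.vertices[region]
    # Voronoi cells are convex; order vertices angularly to be safe
    centre = verts.mean(axis=0)
    order = np.argsort(np.arctan2(verts[:, 1] - centre[1], verts[:, 0] - centre[0]))
    return Polygon(verts[order])


def tessellate_areas(pattern: PointPattern2D,
                     edge_policy: str = "exclude_boundary") -> np.ndarray:
    """Areas (µm²) of the Voronoi polygons of a point pattern.

    ``exclude_boundary`` returns one area per retained interior generator;
    ``clip_to_window`` returns one clipped area per generator.
    """
    if pattern.n < 4:
        raise ValueError("Voronoi tessellation needs at least 4 points")
    pts = pattern.points
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("points are collinear; tessellation is degenerate")

    if edge_policy == "exclude_boundary":
        vor = Voronoi(pts)
        areas = []
        for i in range(len(pts)):
            poly = _region_polygon(vor, i)
            if poly is None:
                continue
            if not pattern.window.contains(poly):
                continue
            areas.append(poly.area)
        return np.asarray(areas)

    if edge_policy == "clip_to_window":
        cells = voronoi_diagram(MultiPoint(pts), envelope=pattern.window)
        areas = np.empty(len(pts))
        tree = shapely.STRtree(list(cells.geoms))
        for i, (x, y) in enumerate(pts):
            j = tree.nearest(shapely.Point(x, y))
            areas[i] = cells.geoms[j].intersection(pattern.window).area
        return areas

    raise ValueError("edge_policy must be 'exclude_boundary' or 'clip_to_window'")


def cv_percent(areas: np.ndarray) -> float:
    """Sample sd (n−1 denominator) over mean, × 100."""
    a = np.asarray(areas, dtype=float)
    if len(a) < 2:
        raise ValueError("CV needs at least 2 areas")
    mean = a.mean()
    if mean <= 0:
        raise ValueError("mean area must be positive")
    return float(np.std(a, ddof=1) / mean * 100.0)


def classify_distribution(cv: float) -> str:
    """Map a polygon-area CV (%) to regular / random / clustered."""
    if cv < 0:
        raise ValueError("CV cannot be negative")
    if cv < REGULAR_MAX_CV:
        return "regular"
    if cv <= RANDOM_MAX_CV:
        return "random"
    return "clustered"


def polygon_area_histogram(areas: np.ndarray,
                           band_edges=(1.0, 50.0)) -> dict[tuple[float, float], float]:
    """Percent of polygons per area band.

    ``band_edges`` are strictly increasing; bands are half-open
    [e_i, e_{i+1}).  Underflow (-inf, e_0) and overflow [e_k, inf) bands are
    appended when any area falls outside, so the percentages always sum to
    100 over the returned bands.
    """
    a = np.asarray(areas, dtype=float)
    if len(a) == 0:
        raise ValueError("no areas to histogram")
    edges = list(band_edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("band edges must be strictly increasing")
    full = [-np.inf] + edges + [np.inf]
    counts, _ = np.histogram(a, bins=full)
    out: dict[tuple[float, float], float] = {}
    for i, c in enumerate(counts):
        lo, hi = full[i], full[i + 1]
        if np.isinf(lo) and c == 0:
            continue
        if np.isinf(hi) and c == 0:
            continue
        out[(lo, hi)] = float(c) / len(a) * 100.0
    return out


def summarize_pattern(pattern: PointPattern2D,
                      edge_policy: str = "exclude_boundary") -> VoronoiSummary:
    """Tessellate, compute the area CV and classify in one call."""
    areas = tessellate_areas(pattern, edge_policy)
    cv = cv_percent(areas)
    return VoronoiSummary(
        polygon_areas=areas,
        mean_area=float(np.mean(areas)),
        cv=cv,
        classification=classify_distribution(cv),
    )
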