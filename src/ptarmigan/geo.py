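"""Geometry kernel: GPS track cleaning, minimum convex polygons, range baselines.

All coordinates are planar metric (projected, e.g. UTM); distances are
Euclidean in meters and areas are reported in km². Geographic (lon/lat)
handling is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from shapely.geometry import MultiPoint
from shapely.geometry.polygon import orient

from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "RangeBaseline",
    "filter_gps_outliers",
    "mcp",
    "radius_from_area",
    "summer_baseline",
]


def radius_from_area(area_km2: float) -> int:
    """Radius (m, rounded to nearest meter) of a circle with the given area.

    Parameters
    ----------
    area_km2 : float
        Circle area in km²; must be positive and finite.

    Returns
    -------
    int
        ``round(sqrt(area * 1e6 / pi))`` in meters.
    """
    if not math.isfinite(area_km2) or area_km2 <= 0:
        raise ValidationError(f"area must be a positive finite number of km², got {area_km2!r}")
    return int(round(math.sqrt(area_km2 * 1e6 / math.pi)))


@dataclass(frozen=True)
class RangeBaseline:
    """Population-level circular home-range baselines and migration threshold.

    The winter and summer baselines are the areas of the circular ranges
    assumed for every bird (winter from GPS-tagged birds' 95% MCPs, summer
    from the median VHF summer polygon). The classification threshold is the
    sum of the two circle radii: two season ranges whose centers lie further
    apart than this cannot overlap.
    """

    winter_area: float = 4.08
    summer_area: float = 0.058
    winter_radius: int = field(init=False)
    summer_radius: int = field(init=False)
    threshold: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "winter_radius", radius_from_area(self.winter_area))
        object.__setattr__(self, "summer_radius", radius_from_area(self.summer_area))
        object.__setattr__(self, "threshold", self.winter_radius + self.summer_radius)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected an (n, 2) array of planar coordinates, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("coordinates must be finite")
    return pts


def filter_gps_outliers(track, timestamps=None) -> tuple[np.ndarray, np.ndarray]:
    """Flag single-fix position spikes in a time-ordered GPS track.

    An interior fix at index ``t`` is an outlier when the step into it is
    more than twice the distance between its two neighbours:
    ``dist(fix[t-1], fix[t]) > 2 * dist(fix[t-1], fix[t+1])``. The first and
    last fixes are never flagged, and the rule is evaluated in a single pass
    over the original sequence (flags do not cascade).

    Parameters
    ----------
    track : array-like, shape (n, 2)
        Fix coordinates in meters, time-ordered, n >= 3.
    timestamps : array-like, optional
        If given, must be strictly increasing.

    Returns
    -------
    retained : ndarray, shape (m, 2)
        Unflagged fixes in original order.
    flagged : ndarray of int
        Indices of flagged fixes in the input track.
    """
    pts = _as_points(track)
    n = len(pts)
    if n < 3:
        raise ValidationError(f"outlier filtering needs at least 3 fixes, got {n}")
    if timestamps is not None:
        ts = np.asarray(timestamps)
        if len(ts) != n:
            raise ValidationError("timestamps length does not match track length")
        if not np.all(ts[1:] > ts[:-1]):
            raise ValidationError("timestamps must be strictly increasing within a GPS track")

    step_in = np.hypot(*(pts[1:-1] - pts[:-2]).T)       # dist(t-1, t)
    spanning = np.hypot(*(pts[2:] - pts[:-2]).T)        # dist(t-1, t+1)
    flagged = np.flatnonzero(step_in > 2.0 * spanning) + 1
    keep = np.ones(n, dtype=bool)
    keep[flagged] = False
    return pts[keep], flagged


def mcp(points, percent: float = 95.0, timestamps=None) -> tuple[np.ndarray, float]:
    """Minimum convex polygon home range.

    Retains the ``k = max(3, floor(percent * n / 100))`` fixes nearest the
    arithmetic mean of all fixes (distance ties broken by earlier timestamp,
    i.e. earlier position in the sequence) and returns the convex hull of the
    retained fixes.

    Parameters
    ----------
    points : array-like, shape (n, 2)
        Fix coordinates in meters.
    percent : float
        Percentage of fixes to retain, in (0, 100].
    timestamps : array-like, optional
        Used only for tie-breaking; defaults to input order, which is
        equivalent for time-sorted fixes.

    Returns
    -------
    vertices : ndarray, shape (v, 2)
        Hull vertices in counter-clockwise order (first vertex not repeated).
    area_km2 : float
        Shoelace area of the hull in km².

    Raises
    ------
    DegenerateGeometryError
        If the retained fixes are collinear (carries ``area_km2 = 0``).
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 3:
        raise ValidationError(f"an MCP needs at least 3 fixes, got {n}")
    if not (0 < percent <= 100):
        raise ValidationError(f"percent must be in (0, 100], got {percent}")

    center = pts.mean(axis=0)
    d = np.hypot(*(pts - center).T)
    if timestamps is not None:
        order = np.lexsort((np.argsort(np.argsort(np.asarray(timestamps), kind="stable")), d))
    else:
        order = np.argsort(d, kind="stable")  # stable sort = earlier fix wins ties
    k = max(3, int(math.floor(percent * n / 100.0)))
    retained = pts[np.sort(order[:k])]

    hull = MultiPoint(retained).convex_hull
    if hull.geom_type != "Polygon":
        raise DegenerateGeometryError(
            f"retained fixes are collinear; no 2-D hull exists (k={k})", area_km2=0.0
        )
    ring = orient(hull, sign=1.0).exterior.coords
    vertices = np.asarray(ring)[:-1]
    return vertices, hull.area / 1e6


def summer_baseline(fix_sets, percent: float = 100.0, min_fixes: int = 3) -> float:
    """Median individual summer home-range area (km²) across birds.

    Each element of ``fix_sets`` is one bird's summer fixes; birds with fewer
    than ``min_fixes`` positions are excluded. The default ``percent=100``
    reproduces the convention of drawing the full polygon over a bird's
    summer positions.
    """
    areas = []
    for fixes in fix_sets:
        pts = np.asarray(fixes, dtype=float)
        if len(pts) < min_fixes:
            continue
        try:
            _, area = mcp(pts, percent=percent)
        except DegenerateGeometryError as err:
            area = err.area_km2
        areas.append(area)
    if not areas:
        raise ValidationError(f"no bird has >= {min_fixes} summer fixes; baseline undefined")
    return float(np.median(areas))
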