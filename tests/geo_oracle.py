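"""Independent geodesic polygon-area oracle for the EOO tests.

Computes the area of the convex polygon enclosing a point set directly
on the sphere: hull ordering from a simple equirectangular projection,
then spherical excess by l'Huilier triangulation from the first vertex.
Shares no code with holohost.geo (which projects to a plane first).
"""

import math

import numpy as np
from scipy.spatial import ConvexHull

RADIUS_KM = 6371.0072


def _gc_dist(p, q):
    """Great-circle distance in radians (haversine)."""
    lon1, lat1, lon2, lat2 = map(math.radians, (*p, *q))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = (math.sin(dlat / 2) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2)
    return 2 * math.asin(min(1.0, math.sqrt(a)))


def _triangle_excess(a, b, c):
    """Spherical excess of a triangle with side lengths a, b, c (radians),
    by l'Huilier's theorem."""
    s = (a + b + c) / 2
    t = (math.tan(s / 2) * math.tan((s - a) / 2)
         * math.tan((s - b) / 2) * math.tan((s - c) / 2))
    return 4 * math.atan(math.sqrt(max(0.0, t)))


def spherical_hull_area_km2(points):
    """Geodesic convex-hull area (km^2) of (lon, lat) degree points."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return 0.0
    latm = math.radians(pts[:, 1].mean())
    flat = np.column_stack([pts[:, 0] * math.cos(latm), pts[:, 1]])
    try:
        hull = ConvexHull(flat)
    except Exception:
        return 0.0
    poly = pts[hull.vertices]
    area = 0.0
    for i in range(1, len(poly) - 1):
        a = _gc_dist(poly[0], poly[i])
        b = _gc_dist(poly[i], poly[i + 1])
        c = _gc_dist(poly[i + 1], poly[0])
        area += _triangle_excess(a, b, c)
    return area * RADIUS_KM ** 2
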