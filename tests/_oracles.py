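"""Independent re-implementations used as test oracles.

These deliberately avoid the package's geometry helpers: the projection
formula is restated locally, convex hulls come from scipy's Qhull, and
aggregations use pandas groupby, so agreement with the package is a real
cross-check rather than a tautology.
"""

import math

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point, Polygon

R_EARTH = 6_371_007.180918475


def project(geom):
    def f(coords):
        lon = np.radians(coords[:, 0])
        lat = np.radians(coords[:, 1])
        return np.column_stack((R_EARTH * lon, R_EARTH * np.sin(lat)))

    return shapely.transform(geom, f)


def in_range_clips(layer, range_geom):
    clips = {}
    for code in layer.african_codes():
        inter = range_geom.intersection(layer.geometry(code))
        if inter.is_empty:
            continue
        proj = project(inter)
        if proj.area > 0:
            clips[code] = proj
    return clips


def hull_of(points):
    """Convex hull via Qhull, degrading to the farthest-pair segment."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 2:
        return LineString(pts)
    try:
        h = ConvexHull(pts)
        return Polygon(pts[h.vertices])
    except QhullError:  # collinear
        d = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        return LineString([pts[i], pts[j]])


def brute_force_inferred(layer, range_geom, observed_countries):
    """Exhaustively test every in-range country polygon against an
    independently computed hull of the observed centroids."""
    clips = in_range_clips(layer, range_geom)
    pts = [
        (clips[c].centroid.x, clips[c].centroid.y)
        for c in sorted(observed_countries)
        if c in clips
    ]
    if len(pts) < 2:
        return set()
    hull = hull_of(pts)
    return {
        code
        for code, clip in clips.items()
        if code not in observed_countries and clip.intersects(hull)
    }


def interpolated_count(layer, range_geom, observed_counts, dest):
    """Independent density-transfer formula from raw geometries."""
    clips = in_range_clips(layer, range_geom)
    areas = {c: g.area for c, g in clips.items()}
    neigh = [
        c
        for c in sorted(observed_counts)
        if c in areas and layer.geometry(c).intersects(layer.geometry(dest))
    ]
    if not neigh:
        dc = clips[dest].centroid
        cands = sorted(
            (c for c in observed_counts if c in areas),
            key=lambda c: (math.hypot(clips[c].centroid.x - dc.x, clips[c].centroid.y - dc.y), c),
        )
        neigh = cands[:2]
    dens = [observed_counts[c] / areas[c] for c in neigh]
    return float(np.mean(dens)) * areas[dest]
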