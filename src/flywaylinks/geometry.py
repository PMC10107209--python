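"""Planar helpers for geographic geometry.

All input geometries are WGS84 longitude/latitude degrees. Areas and
area-weighted centroids are computed after projecting to a cylindrical
equal-area (Lambert) projection on the authalic sphere: the mapping

    x = R * lambda,   y = R * sin(phi)

(with lambda, phi in radians) preserves areas exactly on a sphere of
radius R, so area ratios and area-weighted centroids are unbiased by
latitude, which geographic-degree areas are not.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

#: Authalic Earth radius in metres (sphere with the WGS84 ellipsoid's area).
EARTH_RADIUS_M = 6_371_007.180918475

M2_PER_KM2 = 1e6


def _forward(coords: np.ndarray) -> np.ndarray:
    lon = np.radians(coords[:, 0])
    lat = np.radians(np.clip(coords[:, 1], -90.0, 90.0))
    return np.column_stack((EARTH_RADIUS_M * lon, EARTH_RADIUS_M * np.sin(lat)))


def _inverse(coords: np.ndarray) -> np.ndarray:
    lon = np.degrees(coords[:, 0] / EARTH_RADIUS_M)
    lat = np.degrees(np.arcsin(np.clip(coords[:, 1] / EARTH_RADIUS_M, -1.0, 1.0)))
    return np.column_stack((lon, lat))


def to_equal_area(geom: BaseGeometry) -> BaseGeometry:
    """Project a lon/lat geometry to equal-area planar coordinates (metres)."""
    return shapely.transform(geom, _forward)


def from_equal_area(geom: BaseGeometry) -> BaseGeometry:
    """Inverse of :func:`to_equal_area`."""
    return shapely.transform(geom, _inverse)


def equal_area_km2(geom: BaseGeometry) -> float:
    """Area of a lon/lat geometry in km^2, measured on the authalic sphere."""
    if geom.is_empty:
        return 0.0
    return to_equal_area(geom).area / M2_PER_KM2


def area_weighted_centroid(geom: BaseGeometry) -> Point | None:
    """Area-weighted centroid of a lon/lat geometry, as a lon/lat point.

    The centroid is computed in the equal-area plane (so parts are weighted
    by true area) and mapped back. Returns ``None`` for empty geometry.
    """
    if geom.is_empty:
        return None
    c = to_equal_area(geom).centroid
    return from_equal_area(c)


def repair(geom: BaseGeometry, label: str = "geometry") -> BaseGeometry:
    """Repair an invalid geometry by zero-width buffering.

    Published range polygons routinely contain self-intersecting rings;
    ``buffer(0)`` resolves them while preserving enclosed area. A warning
    is logged whenever a repair actually happened.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if geom.is_valid:
            return geom
        fixed = geom.buffer(0)
    log.warning("repaired invalid geometry for %s (zero-width buffer)", label)
    if fixed.is_empty and not geom.is_empty:
        raise ValueError(f"could not repair invalid geometry for {label}")
    return fixed
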