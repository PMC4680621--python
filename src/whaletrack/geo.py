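"""Spherical geometry shared across the pipeline.

All distances are great-circle distances on a sphere of radius 6371 km;
at Argos error magnitudes the difference from an ellipsoid is negligible.
Longitudes are kept in [0, 360) throughout because the study region
(Coral Sea / Norfolk Ridge, roughly 155° E to 175° W) straddles the
antimeridian.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: kilometres per degree of latitude (and of longitude at the equator)
KM_PER_DEG = 2.0 * np.pi * EARTH_RADIUS_KM / 360.0


def wrap_lon(lon):
    """Wrap longitudes into [0, 360)."""
    return np.asarray(lon, dtype=float) % 360.0


def lon_diff_deg(lon_from, lon_to):
    """Signed smallest longitude difference (lon_to - lon_from) in (-180, 180]."""
    d = (np.asarray(lon_to, dtype=float) - np.asarray(lon_from, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km; symmetric, antimeridian-safe."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def local_xy_km(lon, lat, lon0, lat0):
    """Tangent-plane coordinates (km) around (lon0, lat0).

    Adequate for distances up to a few hundred km, which is the scale at
    which it is used (point-to-isobath distances).
    """
    x = np.radians(lon_diff_deg(lon0, lon)) * EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    y = np.radians(np.asarray(lat, dtype=float) - lat0) * EARTH_RADIUS_KM
    return x, y


def equal_area_xy_km(lon, lat, lon0, lat_std):
    """Cylindrical equal-area projection centred on lon0, standard parallel lat_std.

    Exactly area-preserving: a 10 km x 10 km projected cell corresponds to
    100 km^2 of sphere at every latitude, which is what the occupancy grid
    needs.
    """
    c = np.cos(np.radians(lat_std))
    x = np.radians(lon_diff_deg(lon0, lon)) * EARTH_RADIUS_KM * c
    y = np.sin(np.radians(np.asarray(lat, dtype=float))) * EARTH_RADIUS_KM / c
    return x, y


def equal_area_inverse(x, y, lon0, lat_std):
    """Inverse of :func:`equal_area_xy_km`; returns (lon in [0,360), lat)."""
    c = np.cos(np.radians(lat_std))
    lon = wrap_lon(lon0 + np.degrees(np.asarray(x, dtype=float) / (EARTH_RADIUS_KM * c)))
    s = np.clip(np.asarray(y, dtype=float) * c / EARTH_RADIUS_KM, -1.0, 1.0)
    lat = np.degrees(np.arcsin(s))
    return lon, lat


def point_segments_min_km(px, py, ax, ay, bx, by):
    """Minimum planar distance from point (px,py) to segments (a->b), vectorised."""
    ax = np.asarray(ax, dtype=float)
    vx, vy = np.asarray(bx) - ax, np.asarray(by) - ay
    wx, wy = px - ax, py - np.asarray(ay)
    vv = vx * vx + vy * vy
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(vv > 0, (wx * vx + wy * vy) / vv, 0.0)
    t = np.clip(t, 0.0, 1.0)
    dx = wx - t * vx
    dy = wy - t * vy
    d2 = dx * dx + dy * dy
    return float(np.sqrt(d2.min())) if d2.size else np.inf
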