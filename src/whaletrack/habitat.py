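"""Bathymetric habitat covariates and the ARS-versus-transit comparison.

Each regularized location is annotated with interpolated depth and with
its distance to the 200-m and 500-m isobaths (level-set polylines
extracted by marching squares, minimum great-circle distance to any
contour segment).  Habitats of the two behavioural modes are compared by
one-way ANOVA per covariate; uncertain-mode locations are excluded.

Depths are stored negative-down (ETOPO convention) but summaries report
positive magnitudes, the way depths are quoted in the literature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage import measure

from .bathymetry import BathymetryGrid
from .geo import local_xy_km, point_segments_min_km, wrap_lon

__all__ = [
    "sample_depth",
    "isobath_contours",
    "distance_to_isobath",
    "build_habitat_records",
    "compare_modes",
    "feature_proximity_summary",
]


def sample_depth(bathymetry: BathymetryGrid, lon, lat):
    """Bilinearly interpolated depth (m, negative down) at the query points."""
    return bathymetry.sample(lon, lat)


def isobath_contours(bathymetry: BathymetryGrid, level_m: float):
    """Marching-squares contours of the depth field at -|level_m|.

    Returns a list of (n, 2) arrays of (lon, lat) vertices.  Raises if the
    isobath does not occur within the raster.
    """
    level = -abs(level_m)
    contours = measure.find_contours(bathymetry.depth, level)
    if not contours:
        raise ValueError(f"isobath not present in raster: {level_m} m")
    out = []
    for c in contours:
        # c[:, 0] is the fractional lat index, c[:, 1] the lon index
        lat = np.interp(c[:, 0], np.arange(bathymetry.lat.size), bathymetry.lat)
        lon = np.interp(c[:, 1], np.arange(bathymetry.lon.size), bathymetry.lon)
        out.append(np.stack([lon, lat], axis=1))
    return out


def distance_to_isobath(bathymetry: BathymetryGrid, lon, lat, level_m: float,
                        _contours=None) -> float:
    """Minimum distance (km) from a point to the isobath polyline.

    Segment-accurate: the contour is projected into a tangent plane at the
    query point and the closest point on any segment is used.
    """
    contours = _contours if _contours is not None else isobath_contours(bathymetry, level_m)
    lon = float(wrap_lon(lon))
    best = np.inf
    for c in contours:
        cx, cy = local_xy_km(c[:, 0], c[:, 1], lon, float(lat))
        if len(c) == 1:
            d = float(np.hypot(cx, cy).min())
        else:
            d = point_segments_min_km(0.0, 0.0, cx[:-1], cy[:-1], cx[1:], cy[1:])
        best = min(best, d)
    return float(best)


def build_habitat_records(locations: pd.DataFrame, bathymetry: BathymetryGrid,
                          levels_m=(200.0, 500.0)) -> pd.DataFrame:
    """Per-location habitat covariates.

    Returns columns whale_id, time, mode, depth_m (negative down) and one
    ``dist_<level>m_km`` column per isobath level.
    """
    out = locations[["whale_id", "time", "mode"]].copy()
    out["depth_m"] = np.atleast_1d(bathymetry.sample(locations["lon"].to_numpy(),
                                                     locations["lat"].to_numpy()))
    for level in levels_m:
        contours = isobath_contours(bathymetry, level)
        out[f"dist_{int(level)}m_km"] = [
            distance_to_isobath(bathymetry, lo, la, level, _contours=contours)
            for lo, la in zip(locations["lon"], locations["lat"])]
    return out


def compare_modes(records: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of each habitat covariate between ARS and transit.

    Uncertain-mode records are excluded.  Depth is summarised as positive
    magnitude.  Returns one row per covariate: ARS/transit mean and SD, F
    and p.  If either mode is empty the summaries are still returned with
    F and p as NaN, with a warning.
    """
    from scipy.stats import f_oneway

    rec = records[records["mode"].isin(["ARS", "transit"])]
    covars = [c for c in rec.columns if c == "depth_m" or c.startswith("dist_")]
    rows = []
    for cov in covars:
        vals = rec[cov] if cov != "depth_m" else rec[cov].abs()
        groups = {m: vals[rec["mode"] == m].to_numpy() for m in ("ARS", "transit")}
        row = {"covariate": cov}
        for m, v in groups.items():
            row[f"{m}_mean"] = float(v.mean()) if len(v) else np.nan
            row[f"{m}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
            row[f"{m}_n"] = len(v)
        if all(len(v) >= 2 for v in groups.values()):
            if all(np.ptp(v) == 0 for v in groups.values()) and \
                    groups["ARS"].mean() == groups["transit"].mean():
                row["F"], row["p"] = 0.0, 1.0
            else:
                f, p = f_oneway(groups["ARS"], groups["transit"])
                row["F"], row["p"] = float(f), float(p)
        else:
            warnings.warn(f"one behavioural mode empty for {cov}; "
                          "summaries only, no test", stacklevel=2)
            row["F"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def feature_proximity_summary(locations: pd.DataFrame, sites, radius_km: float = 50.0):
    """Fractions of near-feature locations by behavioural mode.

    A location is "near" when within ``radius_km`` of any site.  Returns a
    dict with fractions for ARS / transit / uncertain over the near
    locations (summing to 1) plus ``n_near``; None if no location is near.
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    lon = locations["lon"].to_numpy(dtype=float)
    lat = locations["lat"].to_numpy(dtype=float)
    near = np.zeros(len(locations), dtype=bool)
    from .geo import great_circle_km

    for s in sites:
        near |= great_circle_km(lon, lat, s.lon, s.lat) <= radius_km
    n_near = int(near.sum())
    if n_near == 0:
        return None
    modes = locations.loc[near, "mode"]
    return {"ARS": float((modes == "ARS").mean()),
            "transit": float((modes == "transit").mean()),
            "uncertain": float((modes == "uncertain").mean()),
            "n_near": n_near}
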