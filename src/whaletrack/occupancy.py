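"""Occupancy-time gridding and consecutive residence near features.

Regularized 12-h locations are binned into a metric grid of 10 km x 10 km
cells (an exactly equal-area cylindrical projection centred on the data).
The occupancy of a cell is

    days_per_whale = (n_positions * 12 h) / 24 / n_whales,

i.e. the total whale-time represented by the positions in the cell
divided by the number of distinct individuals that visited it.  A whale
revisiting a cell still counts once in ``n_whales``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import equal_area_inverse, equal_area_xy_km, great_circle_km

__all__ = ["FeatureSite", "OccupancyGrid", "build_occupancy", "residence_time_days"]


@dataclass
class FeatureSite:
    """A named geographical feature (seamount, bank...) with an association radius."""

    name: str
    lon: float
    lat: float
    radius_km: float = 50.0

    def __post_init__(self):
        if self.radius_km <= 0:
            raise ValueError(f"radius_km must be > 0, got {self.radius_km}")


@dataclass
class OccupancyGrid:
    """Sparse occupancy grid; only visited cells are stored.

    ``cells`` columns: cell_i, cell_j, center_lon, center_lat,
    n_positions, n_whales, days_per_whale.
    """

    cell_size_km: float
    lon0: float
    lat_std: float
    cells: pd.DataFrame

    def total_location_days(self) -> float:
        """Sum over cells of days_per_whale * n_whales (= 0.5 * n positions)."""
        return float((self.cells["days_per_whale"] * self.cells["n_whales"]).sum())

    def to_csv(self, path):
        self.cells.to_csv(path, index=False)

    def to_geojson(self, path=None):
        """Cells as lon/lat polygons with occupancy properties."""
        feats = []
        h = self.cell_size_km
        for _, row in self.cells.iterrows():
            x0, y0 = row["cell_i"] * h, row["cell_j"] * h
            corners = [(x0, y0), (x0 + h, y0), (x0 + h, y0 + h), (x0, y0 + h), (x0, y0)]
            ring = [list(map(float, equal_area_inverse(x, y, self.lon0, self.lat_std)))
                    for x, y in corners]
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {k: (int(row[k]) if k in ("cell_i", "cell_j", "n_positions",
                                                        "n_whales") else float(row[k]))
                               for k in row.index},
            })
        obj = {"type": "FeatureCollection", "features": feats}
        s = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return obj


def build_occupancy(locations: pd.DataFrame, cell_size_km: float = 10.0) -> OccupancyGrid:
    """Grid all whales' regularized locations into equal-area cells.

    ``locations`` needs columns whale_id, lon, lat.  Cell edges are
    half-open with the lower-left edge inclusive.  Empty input yields an
    empty grid.
    """
    if len(locations) == 0:
        empty = pd.DataFrame(columns=["cell_i", "cell_j", "center_lon", "center_lat",
                                      "n_positions", "n_whales", "days_per_whale"])
        return OccupancyGrid(cell_size_km, 0.0, 0.0, empty)

    lon0 = float(locations["lon"].median())
    lat_std = float(locations["lat"].median())
    x, y = equal_area_xy_km(locations["lon"].to_numpy(), locations["lat"].to_numpy(),
                            lon0, lat_std)
    ci = np.floor(x / cell_size_km).astype(int)
    cj = np.floor(y / cell_size_km).astype(int)
    df = pd.DataFrame({"cell_i": ci, "cell_j": cj,
                       "whale_id": locations["whale_id"].to_numpy()})
    agg = (df.groupby(["cell_i", "cell_j"])
           .agg(n_positions=("whale_id", "size"), n_whales=("whale_id", "nunique"))
           .reset_index())
    agg["days_per_whale"] = agg["n_positions"] * 12.0 / 24.0 / agg["n_whales"]
    cx = (agg["cell_i"] + 0.5) * cell_size_km
    cy = (agg["cell_j"] + 0.5) * cell_size_km
    clon, clat = equal_area_inverse(cx.to_numpy(), cy.to_numpy(), lon0, lat_std)
    agg.insert(2, "center_lon", clon)
    agg.insert(3, "center_lat", clat)
    return OccupancyGrid(cell_size_km, lon0, lat_std, agg)


def residence_time_days(locations: pd.DataFrame, site: FeatureSite) -> list:
    """Durations (days) of consecutive stays within the site's radius.

    A stay is a maximal run of consecutive 12-h locations within
    ``site.radius_km`` of the site; its duration is run length x 0.5 days.
    Returned longest-first; empty list if the whale never came close.
    """
    if len(locations) == 0:
        return []
    near = great_circle_km(locations["lon"].to_numpy(), locations["lat"].to_numpy(),
                           site.lon, site.lat) <= site.radius_km
    padded = np.concatenate([[0], near.astype(np.int8), [0]])
    edges = np.flatnonzero(np.diff(padded))
    runs = [(e - s) * 0.5 for s, e in zip(edges[::2], edges[1::2])]
    return sorted(runs, reverse=True)
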