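"""Bathymetry rasters: container, sampling and I/O.

Depths follow the ETOPO convention: metres, negative below sea level
(a 3000-m-deep basin is -3000).  The grid is rectangular in lon/lat with
strictly monotone axes; longitudes are stored in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geo import wrap_lon


@dataclass
class BathymetryGrid:
    """Regular lon/lat depth raster.

    Attributes
    ----------
    lon : 1-D array, degrees in [0, 360), strictly increasing
    lat : 1-D array, degrees, strictly increasing
    depth : 2-D array (lat, lon), metres, negative below sea level
    """

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(np.diff(self.lon) <= 0) or np.any(np.diff(self.lat) <= 0):
            raise ValueError("bathymetry axes must be strictly increasing")
        if self.depth.shape != (self.lat.size, self.lon.size):
            raise ValueError("depth must have shape (n_lat, n_lon)")
        self._interp = RegularGridInterpolator(
            (self.lat, self.lon), self.depth, method="linear", bounds_error=True
        )

    @property
    def cell_deg(self) -> float:
        return float(min(np.diff(self.lon).min(), np.diff(self.lat).min()))

    def contains(self, lon, lat):
        lon = wrap_lon(lon)
        return ((lon >= self.lon[0]) & (lon <= self.lon[-1])
                & (np.asarray(lat) >= self.lat[0]) & (np.asarray(lat) <= self.lat[-1]))

    def sample(self, lon, lat):
        """Bilinearly interpolated depth (m) at the query points.

        Raises ValueError listing offending points if any query lies
        outside the raster extent.
        """
        lon = wrap_lon(lon)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside)).ravel()[:10]
            pts = list(zip(np.atleast_1d(lon)[bad], np.atleast_1d(lat)[bad]))
            raise ValueError(f"points outside bathymetry extent: {pts}")
        out = self._interp(np.stack([np.atleast_1d(lat), np.atleast_1d(lon)], axis=-1))
        return float(out[0]) if np.isscalar(lat) or np.ndim(lat) == 0 else out

    # -- I/O ---------------------------------------------------------------

    def to_dataset(self):
        import xarray as xr

        return xr.Dataset(
            {"depth": (("lat", "lon"), self.depth)},
            coords={"lon": self.lon, "lat": self.lat},
            attrs={"convention": "metres, negative below sea level"},
        )

    def to_netcdf(self, path):
        # scipy backend -> classic netCDF3, dependency-free to read back
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path):
        import xarray as xr

        with xr.open_dataset(path) as ds:
            var = "depth" if "depth" in ds else list(ds.data_vars)[0]
            lon_name = "lon" if "lon" in ds.coords else "x"
            lat_name = "lat" if "lat" in ds.coords else "y"
            lon = wrap_lon(ds[lon_name].values)
            lat = ds[lat_name].values.astype(float)
            depth = ds[var].values.astype(float)
        order_lon = np.argsort(lon)
        order_lat = np.argsort(lat)
        return cls(lon[order_lon], lat[order_lat], depth[np.ix_(order_lat, order_lon)])

    def to_text(self, path):
        """Plain-text grid: header with axes, then one depth row per latitude."""
        with open(path, "w") as fh:
            fh.write(f"# bathymetry grid, metres negative below sea level\n")
            fh.write("lon " + " ".join(f"{v:.6f}" for v in self.lon) + "\n")
            fh.write("lat " + " ".join(f"{v:.6f}" for v in self.lat) + "\n")
            for row in self.depth:
                fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")

    @classmethod
    def from_text(cls, path):
        with open(path) as fh:
            lines = [ln for ln in fh if not ln.startswith("#")]
        lon = np.array(lines[0].split()[1:], dtype=float)
        lat = np.array(lines[1].split()[1:], dtype=float)
        depth = np.array([ln.split() for ln in lines[2:2 + lat.size]], dtype=float)
        return cls(lon, lat, depth)
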