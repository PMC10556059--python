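"""Gridded surface vector fields (currents, winds) and their interpolation.

A :class:`GriddedField` holds u,v (m/s) on a lon x lat x time grid with an
optional land mask, read from or written to CF-style netCDF.  Longitudes are
normalized to [-180, 180) on read (0-360 grids are rolled, values
preserved).  Interpolation is trilinear in lon/lat/time; when some of the
contributing grid nodes are masked (land), the point is flagged "near-land"
and the value is renormalized over the unmasked nodes — masked cells are
never silently treated as zero velocity.

Time is carried as float seconds relative to the file's epoch (the CF units
string is preserved).  A field whose time axis has length 1 is treated as
steady and valid at all query times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import xarray as xr

from .errors import OutOfDomainError, SchemaError, UnitsError

__all__ = ["GriddedField", "read_gridded_field"]

_ACCEPTED_VELOCITY_UNITS = {
    "m s-1", "m s^-1", "m/s", "m s**-1", "meter second-1", "meters second-1",
    "m.s-1", "ms-1", "meter/second", "meters/second",
}

_COORD_ALIASES = {
    "lon": ("lon", "longitude", "LON", "Longitude"),
    "lat": ("lat", "latitude", "LAT", "Latitude"),
    "time": ("time", "TIME", "Time"),
}
_VAR_ALIASES = {
    "u": ("u", "uo", "water_u", "eastward_velocity", "uwnd", "u10"),
    "v": ("v", "vo", "water_v", "northward_velocity", "vwnd", "v10"),
}


class InterpResult(NamedTuple):
    u: np.ndarray
    v: np.ndarray
    near_land: np.ndarray


@dataclass
class GriddedField:
    lon: np.ndarray          # degrees, ascending, [-180, 180)
    lat: np.ndarray          # degrees, ascending
    time: np.ndarray         # seconds (float), ascending
    u: np.ndarray            # (time, lat, lon), m/s, NaN where masked
    v: np.ndarray
    mask: np.ndarray | None = None  # (lat, lon), True = land/missing
    time_units: str = "seconds since 2021-01-01T00:00:00"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time = np.atleast_1d(np.asarray(self.time, dtype=float))
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        shape = (self.time.size, self.lat.size, self.lon.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise SchemaError(
                f"u/v shapes {self.u.shape}/{self.v.shape} do not match "
                f"(time, lat, lon) = {shape}"
            )
        for name, g in (("lon", self.lon), ("lat", self.lat), ("time", self.time)):
            if g.size > 1 and not np.all(np.diff(g) > 0):
                raise SchemaError(f"{name} grid must be strictly ascending")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.lat.size, self.lon.size):
                raise SchemaError("mask must have shape (lat, lon)")

    # -- geometry ---------------------------------------------------------
    @property
    def steady(self) -> bool:
        return self.time.size == 1

    def contains(self, lon, lat, t=None) -> np.ndarray:
        ok = (
            (np.asarray(lon) >= self.lon[0]) & (np.asarray(lon) <= self.lon[-1])
            & (np.asarray(lat) >= self.lat[0]) & (np.asarray(lat) <= self.lat[-1])
        )
        if t is not None and not self.steady:
            ok = ok & (np.asarray(t) >= self.time[0]) & (np.asarray(t) <= self.time[-1])
        return ok

    def cell_masked(self, lon, lat) -> np.ndarray:
        """True where the nearest grid node to each point is masked."""
        if self.mask is None:
            return np.zeros(np.broadcast(lon, lat).shape, dtype=bool)
        i = np.clip(np.searchsorted(self.lon, lon), 1, self.lon.size - 1)
        i = np.where(
            np.abs(np.asarray(lon) - self.lon[i - 1]) <= np.abs(self.lon[i] - np.asarray(lon)),
            i - 1, i,
        )
        j = np.clip(np.searchsorted(self.lat, lat), 1, self.lat.size - 1)
        j = np.where(
            np.abs(np.asarray(lat) - self.lat[j - 1]) <= np.abs(self.lat[j] - np.asarray(lat)),
            j - 1, j,
        )
        return self.mask[j, i]

    # -- interpolation ----------------------------------------------------
    def interp(self, lon, lat, t, out_of_bounds: str = "raise") -> InterpResult:
        """Trilinear interpolation of (u, v) at query points.

        ``out_of_bounds``: "raise" raises :class:`OutOfDomainError`; "nan"
        returns NaN velocity for out-of-domain points (used by the particle
        stepper, which deactivates such particles).  Points whose
        interpolation stencil touches a masked node are flagged near-land
        and renormalized over the unmasked nodes; a fully-masked stencil
        yields NaN.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        t = np.broadcast_to(np.asarray(t, dtype=float), lon.shape)
        oob = ~self.contains(lon, lat, t)
        if np.any(oob):
            if out_of_bounds == "raise":
                raise OutOfDomainError(
                    f"{int(oob.sum())} query point(s) outside field coverage"
                )
            if out_of_bounds != "nan":
                raise ValueError("out_of_bounds must be 'raise' or 'nan'")

        def bracket(grid, x):
            if grid.size == 1:
                return np.zeros(x.shape, dtype=int), np.zeros(x.shape)
            i = np.clip(np.searchsorted(grid, x, side="right") - 1, 0, grid.size - 2)
            w = (x - grid[i]) / (grid[i + 1] - grid[i])
            return i, np.clip(w, 0.0, 1.0)

        i, wx = bracket(self.lon, lon)
        j, wy = bracket(self.lat, lat)
        k, wt = bracket(self.time, t)

        usum = np.zeros(lon.shape)
        vsum = np.zeros(lon.shape)
        wsum = np.zeros(lon.shape)
        any_bad = np.zeros(lon.shape, dtype=bool)
        di_max = 0 if self.lon.size == 1 else 1
        dj_max = 0 if self.lat.size == 1 else 1
        dk_max = 0 if self.steady else 1
        for dk in range(dk_max + 1):
            for dj in range(dj_max + 1):
                for di in range(di_max + 1):
                    w = (
                        (wt if dk else 1 - wt)
                        * (wy if dj else 1 - wy)
                        * (wx if di else 1 - wx)
                    )
                    uu = self.u[k + dk, j + dj, i + di]
                    vv = self.v[k + dk, j + dj, i + di]
                    good = np.isfinite(uu) & np.isfinite(vv)
                    if self.mask is not None:
                        good &= ~self.mask[j + dj, i + di]
                    any_bad |= ~good & (w > 0)
                    w = np.where(good, w, 0.0)
                    usum += w * np.where(good, uu, 0.0)
                    vsum += w * np.where(good, vv, 0.0)
                    wsum += w
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(wsum > 0, usum / wsum, np.nan)
            v = np.where(wsum > 0, vsum / wsum, np.nan)
        near_land = any_bad & (wsum > 0)
        u = np.where(oob, np.nan, u)
        v = np.where(oob, np.nan, v)
        return InterpResult(u=u, v=v, near_land=near_land)

    # -- I/O --------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "u": (("time", "lat", "lon"), self.u, {"units": "m s-1"}),
                "v": (("time", "lat", "lon"), self.v, {"units": "m s-1"}),
            },
            coords={
                "lon": ("lon", self.lon, {"units": "degrees_east"}),
                "lat": ("lat", self.lat, {"units": "degrees_north"}),
                "time": ("time", self.time, {"units": self.time_units}),
            },
            attrs=dict(self.attrs),
        )
        if self.mask is not None:
            ds["mask"] = (("lat", "lon"), self.mask.astype(np.int8),
                          {"long_name": "land/missing mask (1 = masked)"})
        return ds

    def to_netcdf(self, path) -> None:
        # scipy backend -> NETCDF3_CLASSIC; portable and dependency-light
        self.to_dataset().to_netcdf(path, engine="scipy")


def _find_name(candidates, available, kind):
    for name in candidates:
        if name in available:
            return name
    raise SchemaError(f"no {kind} variable found (tried {', '.join(candidates)})")


def read_gridded_field(path, variable_map: dict[str, str] | None = None,
                       unit_converters: dict[str, float] | None = None) -> GriddedField:
    """Read a CF-style gridded velocity file into a :class:`GriddedField`.

    ``variable_map`` may name the file's coordinates/variables, e.g.
    ``{"u": "water_u", "v": "water_v", "lon": "longitude"}``; common aliases
    are tried otherwise.  Velocity units must be m/s unless
    ``unit_converters`` supplies a multiplicative factor for the declared
    unit string.  0-360 longitude grids are normalized to [-180, 180) with
    the data rolled to keep values attached to their coordinates; fill
    values become NaN and a 2-D mask is extracted from cells that are
    missing at every time.
    """
    variable_map = variable_map or {}
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        names = {}
        for key, aliases in {**_COORD_ALIASES, **_VAR_ALIASES}.items():
            names[key] = variable_map.get(key) or _find_name(
                aliases, list(ds.variables), key
            )
        lon = np.asarray(ds[names["lon"]].values, dtype=float)
        lat = np.asarray(ds[names["lat"]].values, dtype=float)
        time = np.atleast_1d(np.asarray(ds[names["time"]].values, dtype=float))
        time_units = str(ds[names["time"]].attrs.get("units", "seconds"))

        u = ds[names["u"]]
        v = ds[names["v"]]
        for var in (u, v):
            units = str(var.attrs.get("units", "")).strip()
            if units and units.lower() not in _ACCEPTED_VELOCITY_UNITS:
                factor = (unit_converters or {}).get(units)
                if factor is None:
                    raise UnitsError(
                        f"variable {var.name!r} declares units {units!r}; expected m/s "
                        "(register a converter to accept it)"
                    )
        uvals = np.asarray(u.values, dtype=float)
        vvals = np.asarray(v.values, dtype=float)
        for var, vals in ((u, uvals), (v, vvals)):
            units = str(var.attrs.get("units", "")).strip()
            factor = (unit_converters or {}).get(units)
            if factor is not None:
                vals *= factor
            fill = var.attrs.get("_FillValue", var.attrs.get("missing_value"))
            if fill is not None:
                vals[vals == float(fill)] = np.nan
        if uvals.ndim == 2:  # single time level stored without a time dim
            uvals = uvals[None]
            vvals = vvals[None]

        if "mask" in ds.variables:
            mask = np.asarray(ds["mask"].values, dtype=bool)
        else:
            missing = ~np.isfinite(uvals) | ~np.isfinite(vvals)
            mask = missing.all(axis=0)
            mask = mask if mask.any() else None

        # normalize 0-360 longitudes, rolling data to keep them attached;
        # grids already in [-180, 180) are kept bit-identical
        if lon.min() >= -180.0 and lon.max() < 180.0:
            lon_norm = lon
        else:
            lon_norm = (lon + 180.0) % 360.0 - 180.0
        if not np.all(np.diff(lon_norm) > 0):
            order = np.argsort(lon_norm, kind="stable")
            lon_norm = lon_norm[order]
            uvals = uvals[:, :, order]
            vvals = vvals[:, :, order]
            if mask is not None:
                mask = mask[:, order]

    return GriddedField(
        lon=lon_norm, lat=lat, time=time, u=uvals, v=vvals,
        mask=mask, time_units=time_units,
    )
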