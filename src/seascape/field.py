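"""Gridded monthly surface velocity fields.

A :class:`VelocityField` holds eastward/northward velocity components on a
regular Cartesian grid for a sequence of calendar months, together with a
land mask. It is the substrate for the Lagrangian transport simulation.
The toy domain is flat: grid columns map to a nominal longitude and rows
to a nominal latitude, with no spherical metric terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = ["VelocityField", "MONTH_LENGTH_S"]

#: One model month: 30 days of 86400 s (a 360-day year).
MONTH_LENGTH_S = 30 * 86400.0


@dataclass
class VelocityField:
    """Monthly u, v velocities (m/s) on a masked Cartesian grid.

    Attributes
    ----------
    u, v : ndarray of shape (n_months, n_rows, n_cols)
        Eastward (u) and northward (v) velocity in m/s; exactly zero on
        land cells.
    dx, dy : float
        Grid spacing in metres (column and row direction).
    landmask : ndarray of bool, shape (n_rows, n_cols)
        True on land cells.
    month_length : float
        Duration of one month in seconds.
    """

    u: np.ndarray
    v: np.ndarray
    dx: float
    dy: float
    landmask: np.ndarray
    month_length: float = MONTH_LENGTH_S

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.landmask = np.asarray(self.landmask, dtype=bool)
        if self.u.shape != self.v.shape or self.u.ndim != 3:
            raise ValueError("u and v must both have shape (n_months, rows, cols)")
        if self.u.shape[1:] != self.landmask.shape:
            raise ValueError("landmask shape does not match velocity grids")
        if self.n_months < 12 or self.n_months % 12 != 0:
            raise ValueError("n_months must be >= 12 and divisible by 12")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacings dx, dy must be positive")
        ocean = ~self.landmask
        if not (np.isfinite(self.u[:, ocean]).all() and np.isfinite(self.v[:, ocean]).all()):
            raise ValueError("velocities must be finite on ocean cells")
        if np.any(self.u[:, self.landmask] != 0) or np.any(self.v[:, self.landmask] != 0):
            raise ValueError("velocities must be zero on land cells")

    @property
    def n_months(self) -> int:
        return self.u.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.landmask.shape

    @property
    def ocean_cells(self) -> np.ndarray:
        """(n_ocean, 2) array of (row, col) indices of ocean cells."""
        return np.argwhere(~self.landmask)

    def mean_field(self) -> tuple[np.ndarray, np.ndarray]:
        """Time-mean u, v over all months."""
        return self.u.mean(axis=0), self.v.mean(axis=0)

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {
                "u": (("month", "row", "col"), self.u),
                "v": (("month", "row", "col"), self.v),
                "landmask": (("row", "col"), self.landmask.astype(np.int8)),
            },
            attrs={
                "dx": float(self.dx),
                "dy": float(self.dy),
                "month_length": float(self.month_length),
            },
        )
        # netCDF-3 via the scipy backend keeps the file dependency-light
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "VelocityField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(
                u=ds["u"].values,
                v=ds["v"].values,
                dx=float(ds.attrs["dx"]),
                dy=float(ds.attrs["dy"]),
                landmask=ds["landmask"].values.astype(bool),
                month_length=float(ds.attrs["month_length"]),
            )
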