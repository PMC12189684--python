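"""Gridded environmental layers on a regular lat/lon grid.

An :class:`EnvStack` holds one 2-D layer per covariate on a shared
cell-center registered grid, north-up in storage-independent form (latitude
ascending in the array; writers flip as needed). Land is encoded as NaN and
must be consistent across layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import xarray as xr

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid, cell-center registration.

    Cell centers run from ``lat_min`` to ``lat_max`` (and likewise for
    longitude) inclusive, spaced ``cell_size`` degrees apart, so a 0.5
    degree grid over 26.5-35 N spans 18 latitude rows.
    """

    lat_min: float = 26.5
    lat_max: float = 35.0
    lon_min: float = 120.0
    lon_max: float = 127.0
    cell_size: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("grid extent must have positive span")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("degenerate grid: zero cells")

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size)) + 1

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size)) + 1

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + self.cell_size * np.arange(self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.cell_size * np.arange(self.n_lon)


@dataclass
class EnvStack:
    """Aligned covariate layers for one season/scenario.

    Parameters
    ----------
    lat, lon : 1-D arrays of cell-center coordinates, ascending.
    layers : mapping covariate name -> 2-D array shaped (n_lat, n_lon);
        NaN marks land, identically across layers.
    season : optional season label the stack represents.
    """

    lat: np.ndarray
    lon: np.ndarray
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    season: str | None = None

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        shape = (self.lat.size, self.lon.size)
        masks = []
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {shape}"
                )
            self.layers[name] = arr
            masks.append(np.isfinite(arr))
        if masks:
            first = masks[0]
            for m, name in zip(masks[1:], list(self.layers)[1:]):
                if not np.array_equal(m, first):
                    raise ValueError(f"land mask of layer {name!r} is inconsistent")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def covariates(self) -> list[str]:
        return list(self.layers)

    @property
    def sea_mask(self) -> np.ndarray:
        """Boolean (n_lat, n_lon) array, True on sea cells."""
        if not self.layers:
            return np.ones(self.shape, dtype=bool)
        return np.isfinite(next(iter(self.layers.values())))

    @property
    def n_sea(self) -> int:
        return int(self.sea_mask.sum())

    def aligned_with(self, other: "EnvStack") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def require_aligned(self, other: "EnvStack") -> None:
        if not self.aligned_with(other):
            raise ValueError("grids are not aligned")

    def copy(self) -> "EnvStack":
        return replace(
            self,
            lat=self.lat.copy(),
            lon=self.lon.copy(),
            layers={k: v.copy() for k, v in self.layers.items()},
        )

    def sea_table(self, covariates: list[str] | None = None):
        """Covariate values at sea cells as a DataFrame with lat/lon columns."""
        import pandas as pd

        covariates = covariates or self.covariates
        mask = self.sea_mask
        ii, jj = np.nonzero(mask)
        data = {"lat": self.lat[ii], "lon": self.lon[jj]}
        for name in covariates:
            if name not in self.layers:
                raise KeyError(f"missing covariate layer {name!r}")
            data[name] = self.layers[name][ii, jj]
        return pd.DataFrame(data)

    def iter_cells(self) -> Iterator[tuple[int, int]]:
        ii, jj = np.nonzero(self.sea_mask)
        yield from zip(ii.tolist(), jj.tolist())

    # ---- I/O ------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {k: (("lat", "lon"), v) for k, v in self.layers.items()},
            coords={"lat": self.lat, "lon": self.lon},
        )
        ds.lat.attrs.update(units="degrees_north", standard_name="latitude")
        ds.lon.attrs.update(units="degrees_east", standard_name="longitude")
        if self.season is not None:
            ds.attrs["season"] = self.season
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "EnvStack":
        return cls(
            lat=ds["lat"].values,
            lon=ds["lon"].values,
            layers={str(k): ds[k].values.astype(float) for k in ds.data_vars},
            season=ds.attrs.get("season"),
        )

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def cell_areas_km2(lat: np.ndarray, cell_size: float) -> np.ndarray:
    """Spherical area of each grid row's cells in km^2.

    For a cell of angular width ``cell_size`` centred at latitude phi the
    area is R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)).
    """
    lat = np.asarray(lat, dtype=float)
    half = cell_size / 2.0
    dlon = np.deg2rad(cell_size)
    top = np.deg2rad(lat + half)
    bot = np.deg2rad(lat - half)
    return EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bot))


def stack_mean(stacks: list[EnvStack], season: str | None = None) -> EnvStack:
    """Cellwise mean of aligned stacks (e.g. four seasons -> annual)."""
    if not stacks:
        raise ValueError("need at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        first.require_aligned(s)
        if set(s.layers) != set(first.layers):
            raise ValueError("stacks carry different covariates")
    layers = {
        name: np.mean([s.layers[name] for s in stacks], axis=0)
        for name in first.layers
    }
    return EnvStack(lat=first.lat.copy(), lon=first.lon.copy(), layers=layers, season=season)
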