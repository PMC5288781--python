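"""Synthetic seascapes: archipelago coastlines, substrate labels and current fields.

The generators here stand in for the two external inputs a dispersal study
needs: a rasterized coastline with per-cell substrate classes (rock, sand or
both), and gridded time-varying surface currents of the kind delivered by
operational ocean models.  Currents are derived from a streamfunction, so the
horizontal flow is non-divergent by construction and particle trajectories in
a single-gyre field follow closed streamlines — which makes the fields usable
as analytic oracles for the advection scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

#: metres per degree of latitude (spherical earth, R = 6371 km)
M_PER_DEG = 2 * math.pi * 6_371_000 / 360.0

SUBSTRATES = ("rock", "sand", "both")


class PlacementError(RuntimeError):
    """Raised when islands cannot be placed inside the grid without overlap."""


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid; coordinates refer to cell centers."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("grid extent must be non-empty")

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    def lons(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    def lats(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing a point, or None outside the grid."""
        i = int(np.floor((lat - self.lat_min) / self.resolution))
        j = int(np.floor((lon - self.lon_min) / self.resolution))
        if 0 <= i < self.n_lat and 0 <= j < self.n_lon:
            return i, j
        return None


@dataclass
class CoastGrid:
    """Coastal cells of an archipelago.

    ``cells`` has one row per coastal cell with columns
    ``cell_id, lon, lat, island, substrate``.  ``land`` is an optional boolean
    (n_lat, n_lon) mask of land cells on the same grid; it is present for
    generated archipelagos and absent for coast tables read from file.
    """

    grid: GridSpec
    cells: pd.DataFrame
    land: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")
        bad = ~self.cells["substrate"].isin(SUBSTRATES)
        if bad.any():
            cid = self.cells.loc[bad, "cell_id"].iloc[0]
            lab = self.cells.loc[bad, "substrate"].iloc[0]
            raise ValueError(f"cell {cid}: unknown substrate label {lab!r}")

    def coastal_mask(self) -> np.ndarray:
        mask = np.zeros((self.grid.n_lat, self.grid.n_lon), dtype=bool)
        i, j = self._indices()
        mask[i, j] = True
        return mask

    def cell_id_raster(self) -> np.ndarray:
        """(n_lat, n_lon) int array mapping grid cells to cell_id (-1 = none)."""
        raster = np.full((self.grid.n_lat, self.grid.n_lon), -1, dtype=int)
        i, j = self._indices()
        raster[i, j] = self.cells["cell_id"].to_numpy()
        return raster

    def _indices(self) -> tuple[np.ndarray, np.ndarray]:
        res = self.grid.resolution
        i = np.floor((self.cells["lat"].to_numpy() - self.grid.lat_min) / res).astype(int)
        j = np.floor((self.cells["lon"].to_numpy() - self.grid.lon_min) / res).astype(int)
        return i, j

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: GridSpec) -> "CoastGrid":
        cells = pd.read_csv(path)
        expected = {"cell_id", "lon", "lat", "island", "substrate"}
        missing = expected - set(cells.columns)
        if missing:
            raise ValueError(f"coast table missing columns {sorted(missing)}")
        return cls(grid=grid, cells=cells)


@dataclass
class CurrentField:
    """Gridded surface velocities, (time, lat, lon), in m/s."""

    grid: GridSpec
    times: np.ndarray  # hours since simulation start
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        shape = (len(self.times), self.grid.n_lat, self.grid.n_lon)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v must have shape {shape}")

    @property
    def time_step_hours(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.inf

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {
                "u": (("time", "lat", "lon"), self.u),
                "v": (("time", "lat", "lon"), self.v),
            },
            coords={"time": self.times, "lat": self.grid.lats(), "lon": self.grid.lons()},
            attrs={"resolution": self.grid.resolution},
        )
        if self.land_mask is not None:
            ds["land_mask"] = (("lat", "lon"), self.land_mask.astype("i1"))
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "CurrentField":
        with xr.open_dataset(path, engine="scipy") as ds:
            lats = ds["lat"].values
            lons = ds["lon"].values
            res = float(ds.attrs["resolution"])
            grid = GridSpec(
                lon_min=float(lons[0] - res / 2),
                lon_max=float(lons[-1] + res / 2),
                lat_min=float(lats[0] - res / 2),
                lat_max=float(lats[-1] + res / 2),
                resolution=res,
            )
            land = ds["land_mask"].values.astype(bool) if "land_mask" in ds else None
            return cls(
                grid=grid,
                times=ds["time"].values.astype(float),
                u=ds["u"].values.astype(float),
                v=ds["v"].values.astype(float),
                land_mask=land,
            )


def make_archipelago(
    n_islands: int,
    grid: GridSpec,
    island_radius_range: tuple[float, float] = (0.04, 0.10),
    substrate_mix: dict[str, float] | None = None,
    seed: int = 0,
    max_retries: int = 2000,
) -> CoastGrid:
    """Place circular islands on the grid and return their coastal cells.

    Island interiors become land; the coastal cells are the ocean cells
    8-adjacent to land, so every island is surrounded by a closed ring
    reachable by drifting particles.  Substrate labels are drawn from
    ``substrate_mix`` (default rock 0.5 / sand 0.3 / both 0.2).
    """
    if n_islands < 1:
        raise ValueError("n_islands must be >= 1")
    mix = dict(substrate_mix or {"rock": 0.5, "sand": 0.3, "both": 0.2})
    unknown = set(mix) - set(SUBSTRATES)
    if unknown:
        raise ValueError(f"unknown substrate classes in mix: {sorted(unknown)}")
    probs = np.array([mix.get(s, 0.0) for s in SUBSTRATES], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("substrate_mix must have positive total probability")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    r_lo, r_hi = island_radius_range
    margin = 2.5 * grid.resolution  # room for the coastal ring inside the grid

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < n_islands:
        if attempts >= max_retries:
            raise PlacementError(
                f"placed {len(centers)}/{n_islands} islands after {max_retries} attempts: "
                "islands must fit inside the grid without overlap "
                "(grid too small or radii too large)"
            )
        attempts += 1
        r = rng.uniform(r_lo, r_hi)
        lon = rng.uniform(grid.lon_min + r + margin, grid.lon_max - r - margin)
        lat = rng.uniform(grid.lat_min + r + margin, grid.lat_max - r - margin)
        ok = all(
            math.hypot(lon - c[0], lat - c[1]) > r + rr + 3 * grid.resolution
            for c, rr in zip(centers, radii)
        )
        if ok:
            centers.append((lon, lat))
            radii.append(r)

    lons = grid.lons()
    lats = grid.lats()
    lon2, lat2 = np.meshgrid(lons, lats)
    land = np.zeros((grid.n_lat, grid.n_lon), dtype=bool)
    owner = np.full((grid.n_lat, grid.n_lon), -1, dtype=int)
    for k, ((clon, clat), r) in enumerate(zip(centers, radii)):
        inside = (lon2 - clon) ** 2 + (lat2 - clat) ** 2 <= r**2
        land |= inside
        owner[inside] = k

    # coastal cells: ocean cells 8-adjacent to land
    padded = np.pad(land, 1)
    neighbor_land = np.zeros_like(land)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neighbor_land |= padded[1 + di : 1 + di + grid.n_lat, 1 + dj : 1 + dj + grid.n_lon]
    coastal = neighbor_land & ~land

    ii, jj = np.nonzero(coastal)
    # island identity: nearest island center (islands are well separated)
    clons = np.array([c[0] for c in centers])
    clats = np.array([c[1] for c in centers])
    d2 = (lons[jj][:, None] - clons) ** 2 + (lats[ii][:, None] - clats) ** 2
    island = d2.argmin(axis=1)
    substrate = rng.choice(SUBSTRATES, size=len(ii), p=probs)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(ii)),
            "lon": lons[jj],
            "lat": lats[ii],
            "island": island,
            "substrate": substrate,
        }
    )
    return CoastGrid(grid=grid, cells=cells, land=land)


def make_current_field(
    grid: GridSpec,
    duration_days: float,
    time_step_hours: float = 24.0,
    gyres: list[tuple[tuple[float, float], float, float]] | None = None,
    mean_flow: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    land_mask: np.ndarray | None = None,
) -> CurrentField:
    """Build a non-divergent current field from a streamfunction.

    Each gyre is ``((lon_center, lat_center), radius_deg, peak_speed_mps)`` and
    contributes a Gaussian streamfunction bump whose azimuthal speed peaks at
    ``peak_speed`` one radius from the center; ``mean_flow`` adds a uniform
    (u0, v0) drift.  Velocities are obtained by central finite differences of
    the streamfunction on a local flat metric, which makes the discrete
    divergence vanish identically at interior cells when ``noise_sd`` is 0.
    Seeded Gaussian noise (per time step and cell) makes the field time-varying.
    """
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    if time_step_hours <= 0:
        raise ValueError("time_step_hours must be positive")
    gyres = gyres or []
    for (_, _), radius, peak in [((g[0][0], g[0][1]), g[1], g[2]) for g in gyres]:
        if abs(peak) > 3.0:
            raise ValueError(f"peak speed {peak} m/s outside plausible ocean range (<= 3 m/s)")
        if radius <= 0:
            raise ValueError("gyre radius must be positive")

    times = np.arange(0.0, duration_days * 24.0 + 1e-9, time_step_hours)
    lat_mid = math.radians(0.5 * (grid.lat_min + grid.lat_max))
    dx = grid.resolution * M_PER_DEG * math.cos(lat_mid)  # metres per cell, zonal
    dy = grid.resolution * M_PER_DEG

    lons = grid.lons()
    lats = grid.lats()
    x = (lons - lons[0]) * M_PER_DEG * math.cos(lat_mid)
    y = (lats - lats[0]) * M_PER_DEG
    x2, y2 = np.meshgrid(x, y)

    u0, v0 = mean_flow
    psi = -u0 * y2 + v0 * x2
    for (clon, clat), radius, peak in gyres:
        cx = (clon - lons[0]) * M_PER_DEG * math.cos(lat_mid)
        cy = (clat - lats[0]) * M_PER_DEG
        sigma = radius * M_PER_DEG
        amp = peak * sigma * math.exp(0.5)  # azimuthal speed peaks at r = sigma
        r2 = (x2 - cx) ** 2 + (y2 - cy) ** 2
        psi = psi + amp * np.exp(-r2 / (2 * sigma**2))

    # u = -dpsi/dy, v = dpsi/dx via central differences (one-sided at edges):
    # the discrete central-difference divergence then cancels exactly.
    u1 = -np.gradient(psi, dy, axis=0)
    v1 = np.gradient(psi, dx, axis=1)

    nt = len(times)
    u = np.broadcast_to(u1, (nt,) + u1.shape).copy()
    v = np.broadcast_to(v1, (nt,) + v1.shape).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        u += rng.normal(0.0, noise_sd, size=u.shape)
        v += rng.normal(0.0, noise_sd, size=v.shape)
    if land_mask is not None:
        u[:, land_mask] = 0.0
        v[:, land_mask] = 0.0
    return CurrentField(grid=grid, times=times, u=u, v=v, land_mask=land_mask)


def discrete_divergence(field: CurrentField, t_index: int = 0) -> np.ndarray:
    """Central-difference divergence du/dx + dv/dy (1/s) at interior cells."""
    lat_mid = math.radians(0.5 * (field.grid.lat_min + field.grid.lat_max))
    dx = field.grid.resolution * M_PER_DEG * math.cos(lat_mid)
    dy = field.grid.resolution * M_PER_DEG
    u = field.u[t_index]
    v = field.v[t_index]
    dudx = (u[1:-1, 2:] - u[1:-1, :-2]) / (2 * dx)
    dvdy = (v[2:, 1:-1] - v[:-2, 1:-1]) / (2 * dy)
    return dudx + dvdy


def substrate_summary(coast: CoastGrid, cell_length_km: float | None = None) -> pd.DataFrame:
    """Per-island substrate composition: counts, coastline lengths, percentages.

    The coastline "amount" of a substrate is its cell count times a cell
    length; by default that length is the zonal great-circle extent of one
    grid cell at the island's mean latitude.
    """
    if coast.cells.empty:
        raise ValueError("coast grid is empty")
    rows = []
    for island, group in coast.cells.groupby("island", sort=True):
        counts = {s: int((group["substrate"] == s).sum()) for s in SUBSTRATES}
        total = len(group)
        if cell_length_km is None:
            lat_mean = math.radians(group["lat"].mean())
            length = coast.grid.resolution * (M_PER_DEG / 1000.0) * math.cos(lat_mean)
        else:
            length = cell_length_km
        rows.append(
            {
                "island": island,
                "n_cells": total,
                "n_rock": counts["rock"],
                "n_sand": counts["sand"],
                "n_both": counts["both"],
                "length_rock_km": counts["rock"] * length,
                "length_sand_km": counts["sand"] * length,
                "length_both_km": counts["both"] * length,
                "pct_rock": 100.0 * counts["rock"] / total,
                "pct_sand": 100.0 * counts["sand"] / total,
                "pct_both": 100.0 * counts["both"] / total,
            }
        )
    return pd.DataFrame(rows).set_index("island")
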