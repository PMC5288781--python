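"""Passive particle release, advection and landing.

Particles are released from the centroids of coastal cells and advected
through the gridded current field with a fourth-order Runge-Kutta scheme;
velocities are interpolated bilinearly in space and linearly in time, and
converted from m/s to degrees/hour with the local metric (the zonal component
scaled by cos(latitude)).  A particle lands the first time it moves into a
coastal or land grid cell other than the cell it currently occupies, and
expires if it is still adrift at the maximum pelagic larval duration (PLD)
or leaves the model domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seascape import CoastGrid, CurrentField, M_PER_DEG

#: first day-of-year (0-based) of each month in a 365-day calendar
_MONTH_START = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])
_MONTH_DAYS = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]

EVENT_COLUMNS = [
    "source_cell",
    "dest_cell",
    "source_island",
    "dest_island",
    "drift_days",
    "distance_km",
    "fate",
]


@dataclass
class ReleaseSchedule:
    """Release entries: one row per (cell_id, release time in hours)."""

    entries: pd.DataFrame  # columns cell_id, t_hours
    interval_hours: float
    season: tuple[int, int]
    years: int


@dataclass
class Trajectory:
    particle_id: int
    lon: np.ndarray
    lat: np.ndarray
    t_hours: np.ndarray


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (array-friendly)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def schedule_releases(
    coast: CoastGrid,
    season: tuple[int, int] = (8, 12),
    interval_hours: float = 12.0,
    years: int = 1,
    rocky_only: bool = True,
) -> ReleaseSchedule:
    """Build the release schedule: every eligible cell, every interval, in season.

    ``season`` is an inclusive (start_month, end_month) window of a 365-day
    calendar; with the defaults particles are released every 12 hours from
    August through December.  ``rocky_only`` restricts the sources to cells
    whose substrate supports rocky-reef habitat (rock or both).
    """
    if coast.cells.empty:
        raise ValueError("coast grid is empty")
    if 24.0 % interval_hours != 0:
        raise ValueError("interval_hours must divide 24")
    if not (1 <= season[0] <= 12 and 1 <= season[1] <= 12 and season[0] <= season[1]):
        raise ValueError("season must be (start_month, end_month) with start <= end")

    if rocky_only:
        eligible = coast.cells[coast.cells["substrate"].isin(("rock", "both"))]
    else:
        eligible = coast.cells
    if eligible.empty:
        raise ValueError("no eligible release cells (rocky_only filtered everything out)")

    day0 = int(_MONTH_START[season[0] - 1])
    day1 = int(_MONTH_START[season[1] - 1]) + _MONTH_DAYS[season[1] - 1]  # exclusive
    per_day = int(24 // interval_hours)
    day_times = []
    for year in range(years):
        for d in range(day0, day1):
            for k in range(per_day):
                day_times.append((year * 365 + d) * 24.0 + k * interval_hours)
    times = np.array(day_times)

    cell_ids = eligible["cell_id"].to_numpy()
    entries = pd.DataFrame(
        {
            "cell_id": np.tile(cell_ids, len(times)),
            "t_hours": np.repeat(times, len(cell_ids)),
        }
    ).sort_values(["t_hours", "cell_id"], ignore_index=True)
    return ReleaseSchedule(entries=entries, interval_hours=interval_hours, season=season, years=years)


class _FieldSampler:
    """Bilinear-in-space, linear-in-time velocity lookup in deg/hour."""

    def __init__(self, field: CurrentField):
        self.field = field
        self.lons = field.grid.lons()
        self.lats = field.grid.lats()

    def __call__(self, t_hours: float, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = self.field
        times = f.times
        if len(times) == 1:
            k0 = k1 = 0
            w = 0.0
        else:
            tc = float(np.clip(t_hours, times[0], times[-1]))
            k0 = int(np.clip(np.searchsorted(times, tc, side="right") - 1, 0, len(times) - 2))
            k1 = k0 + 1
            w = (tc - times[k0]) / (times[k1] - times[k0])

        u = self._bilinear(f.u[k0], lon, lat)
        v = self._bilinear(f.v[k0], lon, lat)
        if k1 != k0 and w > 0:
            u = (1 - w) * u + w * self._bilinear(f.u[k1], lon, lat)
            v = (1 - w) * v + w * self._bilinear(f.v[k1], lon, lat)
        # m/s -> degrees/hour with the local metric
        lat_r = np.radians(lat)
        du = u * 3600.0 / (M_PER_DEG * np.cos(lat_r))
        dv = v * 3600.0 / M_PER_DEG
        return du, dv

    def _bilinear(self, grid2d: np.ndarray, lon, lat) -> np.ndarray:
        xs = (np.asarray(lon, dtype=float) - self.lons[0]) / self.field.grid.resolution
        ys = (np.asarray(lat, dtype=float) - self.lats[0]) / self.field.grid.resolution
        nx = len(self.lons) - 1
        ny = len(self.lats) - 1
        xs = np.clip(xs, 0, nx)
        ys = np.clip(ys, 0, ny)
        j0 = np.clip(np.floor(xs).astype(int), 0, max(nx - 1, 0))
        i0 = np.clip(np.floor(ys).astype(int), 0, max(ny - 1, 0))
        j1 = np.minimum(j0 + 1, nx)
        i1 = np.minimum(i0 + 1, ny)
        fx = xs - j0
        fy = ys - i0
        return (
            grid2d[i0, j0] * (1 - fx) * (1 - fy)
            + grid2d[i0, j1] * fx * (1 - fy)
            + grid2d[i1, j0] * (1 - fx) * fy
            + grid2d[i1, j1] * fx * fy
        )


def _advect_batch(
    lon0: np.ndarray,
    lat0: np.ndarray,
    t0: float,
    field: CurrentField,
    step_hours: float,
    max_days: float,
    coast: CoastGrid,
    record: bool = False,
):
    """RK4-advect a cohort released at the same time; returns landing info.

    Returns dict of arrays: fate ('landed'/'expired'), dest_i, dest_j
    (grid indices of the landing cell, -1 if none), lon, lat (final positions),
    drift_hours, out_of_domain, and optionally the sampled trajectory.
    """
    n = len(lon0)
    sampler = _FieldSampler(field)
    grid = field.grid
    res = grid.resolution

    coastal = coast.coastal_mask()
    land = coast.land if coast.land is not None else np.zeros_like(coastal)
    stop_mask = coastal | land

    lon = np.array(lon0, dtype=float)
    lat = np.array(lat0, dtype=float)
    cur_i = np.floor((lat - grid.lat_min) / res).astype(int)
    cur_j = np.floor((lon - grid.lon_min) / res).astype(int)

    active = np.ones(n, dtype=bool)
    fate = np.array(["expired"] * n, dtype=object)
    dest_i = np.full(n, -1, dtype=int)
    dest_j = np.full(n, -1, dtype=int)
    drift_hours = np.full(n, max_days * 24.0)
    out_of_domain = np.zeros(n, dtype=bool)

    n_steps = int(round(max_days * 24.0 / step_hours))
    traj = [(lon.copy(), lat.copy(), t0)] if record else None
    t = t0
    for _ in range(n_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        lo, la = lon[idx], lat[idx]
        h = step_hours
        k1u, k1v = sampler(t, lo, la)
        k2u, k2v = sampler(t + h / 2, lo + h / 2 * k1u, la + h / 2 * k1v)
        k3u, k3v = sampler(t + h / 2, lo + h / 2 * k2u, la + h / 2 * k2v)
        k4u, k4v = sampler(t + h, lo + h * k3u, la + h * k3v)
        lon[idx] = lo + h / 6 * (k1u + 2 * k2u + 2 * k3u + k4u)
        lat[idx] = la + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        t += h
        if record:
            traj.append((lon.copy(), lat.copy(), t))

        ii = np.floor((lat[idx] - grid.lat_min) / res).astype(int)
        jj = np.floor((lon[idx] - grid.lon_min) / res).astype(int)
        outside = (ii < 0) | (ii >= grid.n_lat) | (jj < 0) | (jj >= grid.n_lon)
        if outside.any():
            gone = idx[outside]
            active[gone] = False
            out_of_domain[gone] = True
            drift_hours[gone] = t - t0
        inside = ~outside
        ins = idx[inside]
        ii, jj = ii[inside], jj[inside]
        moved = (ii != cur_i[ins]) | (jj != cur_j[ins])
        landed = moved & stop_mask[ii, jj]
        if landed.any():
            hit = ins[landed]
            fate[hit] = "landed"
            dest_i[hit] = ii[landed]
            dest_j[hit] = jj[landed]
            drift_hours[hit] = t - t0
            active[hit] = False
        cur_i[ins] = ii
        cur_j[ins] = jj

    return {
        "lon": lon,
        "lat": lat,
        "fate": fate,
        "dest_i": dest_i,
        "dest_j": dest_j,
        "drift_hours": drift_hours,
        "out_of_domain": out_of_domain,
        "traj": traj,
    }


def _dest_cells(coast: CoastGrid, res: dict) -> tuple[np.ndarray, np.ndarray]:
    """Map landing grid cells to coastal cell_ids and islands.

    A particle stopping in a land cell is assigned the nearest coastal cell.
    """
    from scipy.spatial import cKDTree

    grid = coast.grid
    raster = coast.cell_id_raster()
    cells = coast.cells.set_index("cell_id")
    n = len(res["fate"])
    dest_cell = np.full(n, -1, dtype=int)
    landed = res["fate"] == "landed"
    if landed.any():
        ci = res["dest_i"][landed]
        cj = res["dest_j"][landed]
        ids = raster[ci, cj]
        missing = ids < 0  # stopped in a land cell: snap to nearest coastal cell
        if missing.any():
            tree = cKDTree(np.column_stack([coast.cells["lon"], coast.cells["lat"]]))
            lon_c = grid.lon_min + (cj[missing] + 0.5) * grid.resolution
            lat_c = grid.lat_min + (ci[missing] + 0.5) * grid.resolution
            _, nearest = tree.query(np.column_stack([lon_c, lat_c]))
            ids[missing] = coast.cells["cell_id"].to_numpy()[nearest]
        dest_cell[landed] = ids
    island = np.full(n, -1, dtype=object)
    ok = dest_cell >= 0
    if ok.any():
        island[ok] = cells.loc[dest_cell[ok], "island"].to_numpy()
    return dest_cell, island


def advect(
    start: tuple[float, float],
    t0: float,
    field: CurrentField,
    step_hours: float = 1.0,
    max_days: float = 4.0,
    coast: CoastGrid | None = None,
) -> tuple[Trajectory, str, dict]:
    """Advect a single particle, returning its trajectory, fate and landing info."""
    if coast is None:
        empty = pd.DataFrame({"cell_id": [], "lon": [], "lat": [], "island": [], "substrate": []})
        coast = CoastGrid(grid=field.grid, cells=empty.astype({"cell_id": int}))
    if step_hours > field.time_step_hours:
        raise ValueError("step_hours must not exceed the field time step")
    res = _advect_batch(
        np.array([start[0]]), np.array([start[1]]), t0, field, step_hours, max_days, coast, record=True
    )
    lons = np.array([p[0][0] for p in res["traj"]])
    lats = np.array([p[1][0] for p in res["traj"]])
    ts = np.array([p[2] for p in res["traj"]])
    fate = str(res["fate"][0])
    if fate == "expired" and res["out_of_domain"][0]:
        info_fate = {"out_of_domain": True}
    else:
        info_fate = {"out_of_domain": False}
    dest_cell, dest_island = _dest_cells(coast, res)
    info = {
        "dest_cell": int(dest_cell[0]) if dest_cell[0] >= 0 else None,
        "dest_island": dest_island[0] if dest_cell[0] >= 0 else None,
        "drift_days": float(res["drift_hours"][0]) / 24.0,
        "lon": float(res["lon"][0]),
        "lat": float(res["lat"][0]),
        **info_fate,
    }
    k = len(ts) if fate == "expired" else int(round(res["drift_hours"][0] / step_hours)) + 1
    return Trajectory(0, lons[:k], lats[:k], ts[:k]), fate, info


def run_simulation(
    coast: CoastGrid,
    field: CurrentField,
    schedule: ReleaseSchedule,
    max_days: float = 4.0,
    step_hours: float = 1.0,
    seed: int | None = None,
    jitter: float = 0.0,
) -> pd.DataFrame:
    """Release every scheduled particle and record one dispersal event each.

    Returns a DataFrame with columns ``source_cell, dest_cell, source_island,
    dest_island, drift_days, distance_km, fate``; ``dest_*`` are NA for
    particles still adrift at ``max_days``.  Releases are at cell centroids;
    ``jitter`` (degrees, default 0) adds seeded uniform sub-cell offsets.
    """
    t_min, t_max = float(field.times[0]), float(field.times[-1])
    sched_times = schedule.entries["t_hours"]
    if len(sched_times) and (sched_times.min() < t_min or sched_times.max() > t_max):
        raise ValueError(
            f"release times [{sched_times.min()}, {sched_times.max()}] outside "
            f"field time span [{t_min}, {t_max}]"
        )
    cells = coast.cells.set_index("cell_id")
    rng = np.random.default_rng(seed)
    frames = []
    for t0, group in schedule.entries.groupby("t_hours", sort=True):
        ids = group["cell_id"].to_numpy()
        lon0 = cells.loc[ids, "lon"].to_numpy(dtype=float)
        lat0 = cells.loc[ids, "lat"].to_numpy(dtype=float)
        if jitter > 0:
            lon0 = lon0 + rng.uniform(-jitter, jitter, len(ids))
            lat0 = lat0 + rng.uniform(-jitter, jitter, len(ids))
        res = _advect_batch(lon0, lat0, float(t0), field, step_hours, max_days, coast)
        dest_cell, dest_island = _dest_cells(coast, res)
        landed = res["fate"] == "landed"
        dist = np.where(landed, haversine_km(lon0, lat0, res["lon"], res["lat"]), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "source_cell": ids,
                    "dest_cell": np.where(landed, dest_cell, pd.NA),
                    "source_island": cells.loc[ids, "island"].to_numpy(),
                    "dest_island": np.where(landed, dest_island, pd.NA),
                    "drift_days": res["drift_hours"] / 24.0,
                    "distance_km": dist,
                    "fate": res["fate"],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
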