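"""Particle release schedules, RK4 advection and the dispersal simulation."""

import numpy as np
import pandas as pd
import pytest

import larvaldrift as ld


def make_coast(grid, rows):
    cells = pd.DataFrame(rows, columns=["cell_id", "lon", "lat", "island", "substrate"])
    return ld.CoastGrid(grid=grid, cells=cells)


class TestSchedule:
    def test_one_cell_one_day(self, grid):
        coast = make_coast(grid, [(0, 0.0, 16.0, 0, "rock")])
        # January, interval 12 h: 31 days x 2/day
        s = ld.schedule_releases(coast, season=(1, 1), interval_hours=12.0)
        assert len(s.entries) == 62
        day1 = s.entries[s.entries["t_hours"] < 24.0]
        assert len(day1) == 2

    def test_sand_island_contributes_nothing(self, grid):
        coast = make_coast(grid, [(0, 0.0, 16.0, 0, "rock"), (1, 0.2, 16.0, 1, "sand")])
        s = ld.schedule_releases(coast, season=(1, 1))
        assert set(s.entries["cell_id"]) == {0}

    def test_counting_oracle_august_december(self, grid):
        rows = [(i, -0.9 + 0.02 * i, 16.0, 0, "rock") for i in range(10)]
        s = ld.schedule_releases(make_coast(grid, rows), season=(8, 12), interval_hours=12.0, years=1)
        # 10 cells x 153 season days x 2 releases/day
        assert len(s.entries) == 10 * 153 * 2

    def test_all_sand_errors(self, grid):
        coast = make_coast(grid, [(0, 0.0, 16.0, 0, "sand")])
        with pytest.raises(ValueError, match="eligible"):
            ld.schedule_releases(coast)

    def test_entries_sorted_by_time(self, grid):
        rows = [(i, -0.5 + 0.1 * i, 16.0, 0, "rock") for i in range(3)]
        s = ld.schedule_releases(make_coast(grid, rows), season=(2, 3))
        assert (np.diff(s.entries["t_hours"]) >= 0).all()


class TestAdvect:
    def test_constant_velocity_closed_form(self, open_ocean_field):
        traj, fate, info = ld.advect((-1.5, 16.0), 0.0, open_ocean_field, step_hours=1.0, max_days=4.0)
        assert fate == "expired"
        d_km = ld.haversine_km(-1.5, 16.0, info["lon"], info["lat"])
        expected = 0.1 * 86400 * 4 / 1000  # 34.56 km
        assert d_km == pytest.approx(expected, rel=1e-3)
        assert info["lat"] == pytest.approx(16.0, abs=1e-9)

    def test_gyre_conserves_radius(self):
        grid = ld.GridSpec(-1, 1, 15, 17, 0.02)
        field = ld.make_current_field(grid, 10.0, gyres=[((0.0, 16.0), 0.3, 0.5)])
        start = (0.3, 16.0)  # one radius from the center: peak speed, fastest rotation
        traj, fate, info = ld.advect(start, 0.0, field, step_hours=1.0, max_days=4.0)
        r0 = ld.haversine_km(0.0, 16.0, start[0], start[1])
        r = ld.haversine_km(0.0, 16.0, traj.lon, traj.lat)
        assert np.abs(r - r0).max() / r0 < 0.005

    def test_zero_field_expires_in_place(self, grid):
        field = ld.make_current_field(grid, 5.0, mean_flow=(0.0, 0.0))
        coast = make_coast(grid, [(0, 0.0, 16.0, 0, "rock")])
        traj, fate, info = ld.advect((0.0, 16.0), 0.0, field, max_days=2.0, coast=coast)
        assert fate == "expired"
        assert info["lon"] == 0.0 and info["lat"] == 16.0

    def test_out_of_domain_is_flagged_not_raised(self):
        g = ld.GridSpec(-0.2, 0.2, 15.9, 16.1, 0.02)
        field = ld.make_current_field(g, 10.0, mean_flow=(1.0, 0.0))
        traj, fate, info = ld.advect((0.0, 16.0), 0.0, field, max_days=4.0)
        assert fate == "expired"
        assert info["out_of_domain"]

    def test_step_halving_uniform_field(self, open_ocean_field):
        _, _, a = ld.advect((-1.5, 16.0), 0.0, open_ocean_field, step_hours=1.0, max_days=4.0)
        _, _, b = ld.advect((-1.5, 16.0), 0.0, open_ocean_field, step_hours=0.5, max_days=4.0)
        assert ld.haversine_km(a["lon"], a["lat"], b["lon"], b["lat"]) < 1e-9

    def test_step_halving_gyre_field(self):
        grid = ld.GridSpec(-1, 1, 15, 17, 0.02)
        field = ld.make_current_field(grid, 10.0, gyres=[((0.0, 16.0), 0.3, 0.5)])
        _, _, a = ld.advect((0.3, 16.0), 0.0, field, step_hours=1.0, max_days=4.0)
        _, _, b = ld.advect((0.3, 16.0), 0.0, field, step_hours=0.5, max_days=4.0)
        assert ld.haversine_km(a["lon"], a["lat"], b["lon"], b["lat"]) < 0.1

    def test_step_exceeding_field_step_rejected(self, grid):
        field = ld.make_current_field(grid, 5.0, time_step_hours=6.0)
        with pytest.raises(ValueError, match="step_hours"):
            ld.advect((0.0, 16.0), 0.0, field, step_hours=12.0, max_days=1.0)


@pytest.fixture(scope="module")
def two_island_setup():
    """Source island due west of a target island at the same latitude."""
    grid = ld.GridSpec(-1, 1, 15, 17, 0.02)
    lons, lats = np.meshgrid(grid.lons(), grid.lats())
    land = np.zeros((grid.n_lat, grid.n_lon), dtype=bool)
    centers = [(-0.6, 16.0), (0.6, 16.0)]
    for clon, clat in centers:
        land |= (lons - clon) ** 2 + (lats - clat) ** 2 <= 0.1**2
    padded = np.pad(land, 1)
    near = np.zeros_like(land)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            near |= padded[1 + di : 1 + di + grid.n_lat, 1 + dj : 1 + dj + grid.n_lon]
    coastal = near & ~land
    ii, jj = np.nonzero(coastal)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(ii)),
            "lon": grid.lons()[jj],
            "lat": grid.lats()[ii],
            "island": (grid.lons()[jj] > 0).astype(int),
            "substrate": "rock",
        }
    )
    coast = ld.CoastGrid(grid=grid, cells=cells, land=land)
    field = ld.make_current_field(grid, 10.0, mean_flow=(0.5, 0.0))
    return coast, field


class TestSimulation:
    def test_strong_eastward_flow_lands_on_target_west_coast(self, two_island_setup):
        coast, field = two_island_setup
        src = coast.cells[coast.cells["island"] == 0]
        entries = pd.DataFrame({"cell_id": src["cell_id"], "t_hours": 0.0})
        schedule = ld.ReleaseSchedule(entries=entries, interval_hours=24.0, season=(1, 1), years=1)
        events = ld.run_simulation(coast, field, schedule, max_days=4.0)
        crossed = events[(events["fate"] == "landed") & (events["dest_island"] == 1)]
        assert len(crossed) > 0
        dest_lons = coast.cells.set_index("cell_id").loc[crossed["dest_cell"], "lon"]
        # landing cells sit on the western (upstream) half of the target island
        east_lons = coast.cells[coast.cells["island"] == 1]["lon"]
        assert (dest_lons <= east_lons.median()).all()

    def test_zero_field_all_expired(self, archipelago, grid):
        field = ld.make_current_field(grid, 5.0, mean_flow=(0.0, 0.0))
        src = archipelago.cells.head(5)
        entries = pd.DataFrame({"cell_id": src["cell_id"], "t_hours": 0.0})
        schedule = ld.ReleaseSchedule(entries=entries, interval_hours=24.0, season=(1, 1), years=1)
        events = ld.run_simulation(archipelago, field, schedule, max_days=1.0)
        assert (events["fate"] == "expired").all()
        assert events["dest_cell"].isna().all()

    def test_events_match_per_particle_advection(self, archipelago, gyre_field):
        src = archipelago.cells.head(2)
        entries = pd.DataFrame({"cell_id": src["cell_id"], "t_hours": 0.0})
        schedule = ld.ReleaseSchedule(entries=entries, interval_hours=24.0, season=(1, 1), years=1)
        events = ld.run_simulation(archipelago, gyre_field, schedule, max_days=2.0)
        for _, ev in events.iterrows():
            row = archipelago.cells.set_index("cell_id").loc[ev["source_cell"]]
            _, fate, info = ld.advect(
                (row["lon"], row["lat"]), 0.0, gyre_field, max_days=2.0, coast=archipelago
            )
            assert fate == ev["fate"]
            if fate == "landed":
                assert info["dest_cell"] == ev["dest_cell"]
                assert info["drift_days"] == pytest.approx(ev["drift_days"])

    def test_landed_invariants(self, archipelago, gyre_field):
        entries = pd.DataFrame({"cell_id": archipelago.cells["cell_id"], "t_hours": 12.0})
        schedule = ld.ReleaseSchedule(entries=entries, interval_hours=24.0, season=(1, 1), years=1)
        events = ld.run_simulation(archipelago, gyre_field, schedule, max_days=3.0)
        landed = events[events["fate"] == "landed"]
        assert (landed["drift_days"] <= 3.0).all()
        assert (landed["drift_days"] > 0).all()
        assert landed["dest_cell"].notna().all()
        # every landing cell is a coastal cell of some island
        assert landed["dest_cell"].isin(archipelago.cells["cell_id"]).all()
        # no expired event carries a destination
        assert events.loc[events["fate"] == "expired", "dest_cell"].isna().all()

    def test_determinism(self, archipelago, gyre_field):
        entries = pd.DataFrame({"cell_id": archipelago.cells["cell_id"].head(10), "t_hours": 0.0})
        schedule = ld.ReleaseSchedule(entries=entries, interval_hours=24.0, season=(1, 1), years=1)
        a = ld.run_simulation(archipelago, gyre_field, schedule, max_days=2.0, seed=5)
        b = ld.run_simulation(archipelago, gyre_field, schedule, max_days=2.0, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_release_outside_field_span_rejected(self, archipelago, gyre_field):
        entries = pd.DataFrame({"cell_id": [int(archipelago.cells["cell_id"].iloc[0])], "t_hours": 1e6})
        schedule = ld.ReleaseSchedule(entries=entries, interval_hours=24.0, season=(1, 1), years=1)
        with pytest.raises(ValueError, match="time span"):
            ld.run_simulation(archipelago, gyre_field, schedule, max_days=1.0)
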