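"""Connectivity aggregation, dispersal summaries and the printed-matrix format."""

import numpy as np
import pandas as pd
import pytest

import larvaldrift as ld
from larvaldrift.connectivity import MatrixParseError
from larvaldrift.lagrangian import ReleaseSchedule


def schedule_of(counts: dict[int, int]) -> ReleaseSchedule:
    rows = [{"cell_id": c, "t_hours": float(i)} for c, n in counts.items() for i in range(n)]
    return ReleaseSchedule(entries=pd.DataFrame(rows), interval_hours=1.0, season=(1, 1), years=1)


def events_frame(rows):
    cols = ["source_cell", "dest_cell", "source_island", "dest_island", "drift_days", "distance_km", "fate"]
    return pd.DataFrame(rows, columns=cols)


def coast_of(mapping: dict[int, object]) -> ld.CoastGrid:
    grid = ld.GridSpec(-1, 1, 15, 17, 0.02)
    cells = pd.DataFrame(
        {
            "cell_id": list(mapping),
            "lon": np.linspace(-0.9, 0.9, len(mapping)),
            "lat": 16.0,
            "island": list(mapping.values()),
            "substrate": "rock",
        }
    )
    return ld.CoastGrid(grid=grid, cells=cells)


class TestCellConnectivity:
    def test_simple_ratio(self):
        ev = events_frame(
            [(0, 1, "a", "b", 1.0, 5.0, "landed")] * 3
            + [(0, pd.NA, "a", pd.NA, 10.0, np.nan, "expired")] * 7
        )
        P = ld.cell_connectivity(ev, schedule_of({0: 10, 1: 10}))
        assert P.loc[0, 1] == pytest.approx(0.3)

    def test_no_landings_gives_zero_matrix(self):
        ev = events_frame([(0, pd.NA, "a", pd.NA, 1.0, np.nan, "expired")] * 4)
        P = ld.cell_connectivity(ev, schedule_of({0: 4}))
        assert (P.to_numpy() == 0).all()

    def test_matches_hash_count_oracle(self):
        rng = np.random.default_rng(0)
        cells = list(range(6))
        rows = []
        released = {c: 0 for c in cells}
        for _ in range(500):
            src = int(rng.choice(cells))
            released[src] += 1
            if rng.random() < 0.6:
                dst = int(rng.choice(cells))
                rows.append((src, dst, 0, 0, 1.0, 1.0, "landed"))
            else:
                rows.append((src, pd.NA, 0, pd.NA, 4.0, np.nan, "expired"))
        ev = events_frame(rows)
        P = ld.cell_connectivity(ev, schedule_of(released))
        # independent tally
        tally: dict[tuple[int, int], int] = {}
        for r in rows:
            if r[6] == "landed":
                tally[(r[0], r[1])] = tally.get((r[0], r[1]), 0) + 1
        for (a, b), k in tally.items():
            assert P.loc[a, b] == pytest.approx(k / released[a])

    def test_unscheduled_source_rejected(self):
        ev = events_frame([(99, 1, "a", "b", 1.0, 5.0, "landed")])
        with pytest.raises(ValueError, match="unscheduled"):
            ld.cell_connectivity(ev, schedule_of({0: 1, 1: 1}))

    def test_row_sums_at_most_one(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(300):
            src = int(rng.integers(0, 4))
            if rng.random() < 0.8:
                rows.append((src, int(rng.integers(0, 4)), 0, 0, 1.0, 1.0, "landed"))
            else:
                rows.append((src, pd.NA, 0, pd.NA, 4.0, np.nan, "expired"))
        ev = events_frame(rows)
        released = ev.groupby("source_cell").size().to_dict()
        P = ld.cell_connectivity(ev, schedule_of(released))
        assert (P.sum(axis=1) <= 1.0 + 1e-12).all()


class TestIslandConnectivity:
    def test_one_cell_per_island_equals_cell_matrix(self):
        coast = coast_of({0: "A", 1: "B"})
        P = pd.DataFrame([[0.0, 0.25], [0.1, 0.0]], index=[0, 1], columns=[0, 1])
        M = ld.island_connectivity(P, coast)
        assert M.df.loc["A", "B"] == pytest.approx(0.25)
        assert M.df.loc["B", "A"] == pytest.approx(0.1)

    def test_uniform_probabilities_average_to_same(self):
        coast = coast_of({0: "A", 1: "A", 2: "B"})
        P = pd.DataFrame(
            [[0, 0, 0.2], [0, 0, 0.2], [0.05, 0.05, 0]], index=[0, 1, 2], columns=[0, 1, 2]
        )
        M = ld.island_connectivity(P, coast)
        assert M.df.loc["A", "B"] == pytest.approx(0.2)
        assert M.df.loc["B", "A"] == pytest.approx(0.1)  # 0.05 + 0.05 summed over A's cells

    def test_three_island_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        mapping = {i: "ABC"[i % 3] for i in range(9)}
        coast = coast_of(mapping)
        P = pd.DataFrame(rng.uniform(0, 0.01, (9, 9)), index=range(9), columns=range(9))
        M = ld.island_connectivity(P, coast)
        for I in "ABC":
            for J in "ABC":
                if I == J:
                    continue
                srcs = [c for c, isl in mapping.items() if isl == I]
                dsts = [c for c, isl in mapping.items() if isl == J]
                expected = np.mean([sum(P.loc[a, b] for b in dsts) for a in srcs])
                assert M.df.loc[I, J] == pytest.approx(expected, abs=1e-15)

    def test_permutation_invariance_of_pipeline(self):
        rng = np.random.default_rng(5)
        rows = []
        for _ in range(200):
            src = int(rng.integers(0, 6))
            if rng.random() < 0.5:
                rows.append((src, int(rng.integers(0, 6)), 0, 0, 1.0, 1.0, "landed"))
            else:
                rows.append((src, pd.NA, 0, pd.NA, 4.0, np.nan, "expired"))
        ev = events_frame(rows)
        released = ev.groupby("source_cell").size().to_dict()
        coast = coast_of({i: "AB"[i % 2] for i in range(6)})
        sched = schedule_of(released)
        direct = ld.island_connectivity(ld.cell_connectivity(ev, sched), coast)
        shuffled = ld.island_connectivity(
            ld.cell_connectivity(ev.sample(frac=1.0, random_state=9), sched), coast
        )
        np.testing.assert_allclose(direct.P, shuffled.P)


class TestSummarize:
    def test_single_event(self):
        ev = events_frame([(0, 1, "a", "b", 2.0, 10.0, "landed")])
        s = ld.summarize(ev)
        assert s.max_distance == s.mean_distance == 10.0
        assert s.sd_distance == 0.0
        assert s.max_time == s.mean_time == 2.0

    def test_self_cell_events_excluded(self):
        ev = events_frame([(0, 0, "a", "a", 1.0, 0.5, "landed")] * 5)
        s = ld.summarize(ev)
        assert np.isnan(s.mean_distance)
        assert s.n_events == 0

    def test_against_direct_formulas(self):
        rng = np.random.default_rng(7)
        rows = []
        for _ in range(1000):
            src = int(rng.integers(0, 10))
            if rng.random() < 0.7:
                dst = int(rng.integers(0, 10))
                rows.append((src, dst, 0, 0, rng.uniform(0.5, 4), rng.uniform(1, 300), "landed"))
            else:
                rows.append((src, pd.NA, 0, pd.NA, 4.0, np.nan, "expired"))
        ev = events_frame(rows)
        s = ld.summarize(ev)
        eff = [r for r in rows if r[6] == "landed" and r[0] != r[1]]
        dists = np.array([r[5] for r in eff])
        times = np.array([r[4] for r in eff])
        assert s.mean_distance == pytest.approx(dists.mean(), abs=1e-12)
        assert s.sd_distance == pytest.approx(dists.std(ddof=1), abs=1e-12)
        assert s.max_time == pytest.approx(times.max(), abs=1e-12)
        released = {}
        for r in rows:
            released[r[0]] = released.get(r[0], 0) + 1
        pairs = {}
        for r in eff:
            pairs[(r[0], r[1])] = pairs.get((r[0], r[1]), 0) + 1
        probs = np.array([k / released[a] for (a, _), k in pairs.items()])
        assert s.mean_probability == pytest.approx(probs.mean(), abs=1e-12)
        assert s.max_probability == pytest.approx(probs.max(), abs=1e-12)

    def test_summary_ordering_invariant(self):
        ev = events_frame(
            [(0, 1, "a", "b", 1.0, 10.0, "landed"), (1, 0, "b", "a", 3.0, 50.0, "landed")]
        )
        s = ld.summarize(ev)
        assert s.max_distance >= s.mean_distance >= 0
        assert s.max_time >= s.mean_time >= 0


class TestMatrixIO:
    def test_table2_printed_values(self, table2):
        assert table2.df.loc["Santo Antao", "Maio"] == pytest.approx(2.30e-06)
        assert table2.df.loc["Sao Vincente", "Santo Antao"] == pytest.approx(2.20e-03)

    def test_table2_minimum_is_the_printed_lower_bound(self, table2):
        assert table2.min_offdiag() == pytest.approx(2.3e-06)

    def test_roundtrip_random_matrix(self, tmp_path):
        rng = np.random.default_rng(2)
        P = rng.uniform(0, 0.01, (9, 9))
        np.fill_diagonal(P, np.nan)
        labels = [f"isl{i}" for i in range(9)]
        m = ld.ConnectivityMatrix(labels=labels, P=P)
        path = tmp_path / "m.csv"
        ld.write_matrix(m, path)
        back = ld.read_matrix(path)
        assert back.labels == labels
        off = ~np.eye(9, dtype=bool)
        np.testing.assert_array_equal(back.P[off], P[off])

    def test_export_format_matches_print_style(self, table2, tmp_path):
        path = tmp_path / "t2.csv"
        ld.write_matrix(table2, path, fmt="%.2E")
        text = path.read_text()
        assert "2.30E-06" in text
        assert "—" in text

    def test_label_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",A,B\nA,—,1e-3\nC,1e-3,—\n")
        with pytest.raises(MatrixParseError, match="labels"):
            ld.read_matrix(path)

    def test_non_numeric_cell_reported_with_context(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",A,B\nA,—,oops\nB,1e-3,—\n")
        with pytest.raises(MatrixParseError, match="row 'A', column 'B'"):
            ld.read_matrix(path)
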