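"""Connectivity matrices and dispersal summaries.

Cell-level connectivity is the fraction of particles released from a source
cell that land on each destination cell; island-level connectivity averages,
over the source island's release cells, each cell's total probability of
landing anywhere on the destination island ("mean connectivity").  Matrices
are directed (rows = source island, columns = destination) and generally
asymmetric; the diagonal (self-recruitment) is left undefined and written as
an em dash, matching the layout of published island connectivity tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .seascape import CoastGrid


class MatrixParseError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """Directed island-to-island connectivity probabilities.

    ``P[i, j]`` is the mean probability that a particle released from island
    ``labels[i]`` lands on island ``labels[j]``; the diagonal is NaN.
    """

    labels: list[str]
    P: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("island labels must be unique")
        off = ~np.eye(len(self.labels), dtype=bool)
        vals = self.P[off]
        vals = vals[~np.isnan(vals)]
        if len(vals) and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("connectivity probabilities must lie in [0, 1]")

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.labels, columns=self.labels)

    def min_offdiag(self) -> float:
        off = ~np.eye(len(self.labels), dtype=bool)
        return float(np.nanmin(self.P[off]))

    def max_offdiag(self) -> float:
        off = ~np.eye(len(self.labels), dtype=bool)
        return float(np.nanmax(self.P[off]))


@dataclass
class DispersalSummary:
    """Distance / probability / drift-time statistics of effective dispersal.

    Statistics cover landed particles whose destination cell differs from the
    source cell; probabilities are per connected (source, destination) cell
    pair.  All fields are NaN when no such event exists.
    """

    max_distance: float
    mean_distance: float
    sd_distance: float
    max_probability: float
    mean_probability: float
    sd_probability: float
    max_time: float
    mean_time: float
    sd_time: float
    n_events: int


def cell_connectivity(events: pd.DataFrame, schedule) -> pd.DataFrame:
    """Cell-level directed probability matrix: landed(a->b) / released(a)."""
    released = schedule.entries["cell_id"].value_counts()
    extra = set(events["source_cell"].unique()) - set(released.index)
    if extra:
        raise ValueError(f"events reference unscheduled source cells: {sorted(extra)[:5]}")
    if (released == 0).any():
        raise ValueError("schedule contains cells with zero releases")
    sources = sorted(released.index)
    landed = events[(events["fate"] == "landed") & events["dest_cell"].notna()]
    dests = sorted(set(sources) | set(int(d) for d in landed["dest_cell"].unique()))
    P = pd.DataFrame(0.0, index=sources, columns=dests)
    if not landed.empty:
        counts = landed.groupby(["source_cell", landed["dest_cell"].astype(int)]).size()
        for (a, b), k in counts.items():
            P.loc[a, b] = k / released[a]
    return P


def island_connectivity(
    cell_matrix: pd.DataFrame,
    coast: CoastGrid,
    how: str = "mean",
    schedule=None,
    metadata: dict | None = None,
) -> ConnectivityMatrix:
    """Aggregate a cell-level matrix to island level.

    ``how='mean'`` (the default) averages, over the source island's release
    cells, each cell's total probability of landing on the destination
    island; ``how='pooled'`` instead pools particle counts, weighting each
    source cell by its number of releases (requires ``schedule``).
    """
    cell_to_island = coast.cells.set_index("cell_id")["island"]
    missing = set(cell_matrix.index) - set(cell_to_island.index)
    missing |= set(cell_matrix.columns) - set(cell_to_island.index)
    if missing:
        raise ValueError(f"cells not present in coast grid: {sorted(missing)[:5]}")

    islands = sorted(pd.unique(cell_to_island), key=str)
    src_island = cell_to_island.loc[cell_matrix.index]
    dst_island = cell_to_island.loc[cell_matrix.columns]
    # total probability of landing anywhere on each destination island
    by_dest = cell_matrix.T.groupby(dst_island.to_numpy()).sum().T  # rows cells, cols islands

    n = len(islands)
    P = np.full((n, n), np.nan)
    flagged = []
    for i, isl in enumerate(islands):
        rows = by_dest[src_island.to_numpy() == isl]
        if rows.empty:
            flagged.append(isl)
            continue
        if how == "mean":
            agg = rows.mean(axis=0)
        elif how == "pooled":
            if schedule is None:
                raise ValueError("how='pooled' requires the release schedule")
            w = schedule.entries["cell_id"].value_counts().reindex(rows.index).fillna(0.0)
            agg = (rows.mul(w, axis=0)).sum(axis=0) / w.sum()
        else:
            raise ValueError(f"unknown aggregation {how!r}")
        for j, jsl in enumerate(islands):
            if i != j and jsl in agg.index:
                P[i, j] = float(agg[jsl])
    meta = dict(metadata or {})
    meta["aggregation"] = how
    if flagged:
        meta["islands_without_sources"] = flagged
    return ConnectivityMatrix(labels=[str(i) for i in islands], P=P, metadata=meta)


def summarize(events: pd.DataFrame) -> DispersalSummary:
    """Table-1-style statistics over effective (different-cell) dispersal events."""
    nan = float("nan")
    if events.empty:
        return DispersalSummary(*([nan] * 9), n_events=0)
    eff = events[
        (events["fate"] == "landed")
        & events["dest_cell"].notna()
        & (events["dest_cell"].astype("Int64") != events["source_cell"].astype("Int64"))
    ]
    if eff.empty:
        return DispersalSummary(*([nan] * 9), n_events=0)
    dist = eff["distance_km"].to_numpy(dtype=float)
    time = eff["drift_days"].to_numpy(dtype=float)
    # per-pair connection probability: landed(a->b) / released(a)
    released = events.groupby("source_cell").size()
    pair_counts = eff.groupby(["source_cell", eff["dest_cell"].astype(int)]).size()
    probs = np.array([k / released[a] for (a, _), k in pair_counts.items()], dtype=float)
    return DispersalSummary(
        max_distance=float(dist.max()),
        mean_distance=float(dist.mean()),
        sd_distance=float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
        max_probability=float(probs.max()),
        mean_probability=float(probs.mean()),
        sd_probability=float(probs.std(ddof=1)) if len(probs) > 1 else 0.0,
        max_time=float(time.max()),
        mean_time=float(time.mean()),
        sd_time=float(time.std(ddof=1)) if len(time) > 1 else 0.0,
        n_events=int(len(eff)),
    )


_DASHES = {"—", "-", "--", ""}


def read_matrix(path) -> ConnectivityMatrix:
    """Read a labelled island connectivity matrix from delimited text.

    The format is the published one: a header row of island names, one row
    per source island, and an em dash on the diagonal.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    labels = [str(c).strip() for c in df.columns]
    row_labels = [str(r).strip() for r in df.index]
    if labels != row_labels:
        raise MatrixParseError(
            f"row labels {row_labels} do not match column labels {labels}"
        )
    n = len(labels)
    P = np.full((n, n), np.nan)
    for i, r in enumerate(row_labels):
        for j, c in enumerate(labels):
            raw = str(df.iloc[i, j]).strip()
            if i == j:
                if raw not in _DASHES and raw.lower() != "nan":
                    raise MatrixParseError(f"diagonal cell ({r}, {c}) should be blank, got {raw!r}")
                continue
            try:
                P[i, j] = float(raw)
            except ValueError as exc:
                raise MatrixParseError(f"non-numeric value {raw!r} at row {r!r}, column {c!r}") from exc
    return ConnectivityMatrix(labels=labels, P=P, metadata={"source": str(path)})


def write_matrix(matrix: ConnectivityMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix in the published layout; ``fmt='%.2E'`` mimics print style."""
    n = len(matrix.labels)
    out = []
    for i in range(n):
        row = []
        for j in range(n):
            if i == j or np.isnan(matrix.P[i, j]):
                row.append("—")
            elif fmt:
                row.append(fmt % matrix.P[i, j])
            else:
                row.append(repr(float(matrix.P[i, j])))
        out.append(row)
    pd.DataFrame(out, index=matrix.labels, columns=matrix.labels).to_csv(path)


def load_table2() -> ConnectivityMatrix:
    """Packaged 4-day mean island connectivity matrix (printed data)."""
    with resources.as_file(resources.files("larvaldrift.data") / "table2_4day.csv") as p:
        m = read_matrix(p)
    m.metadata.update({"pld_days": 4, "source": "table2_4day.csv"})
    return m


def load_table3() -> ConnectivityMatrix:
    """Packaged 30-day mean island connectivity matrix (printed data)."""
    with resources.as_file(resources.files("larvaldrift.data") / "table3_30day.csv") as p:
        m = read_matrix(p)
    m.metadata.update({"pld_days": 30, "source": "table3_30day.csv"})
    return m
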