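"""Lagrangian surface transport and minimum travel times.

Floats are advected on the gridded velocity field with a fourth-order
Runge-Kutta scheme (velocities interpolated bilinearly in space and
linearly in time) plus an additive Gaussian kick per step representing
horizontal eddy diffusivity K (standard deviation ``sqrt(2 K dt)`` per
component). Monthly trajectories released in every ocean cell are
precomputed once per calendar-month instance and then stitched into
multi-year paths: each stitched trajectory follows a monthly trajectory
to its end cell and continues with a randomly chosen stored trajectory
of the following calendar month starting in that cell.

The directed minimum travel time ``T_min[i, j]`` between stations is the
minimum, over all trajectories released near station i, of the first
time the trajectory enters the capture disc of station j; pairs with too
few connecting trajectories are masked as unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .field import VelocityField

__all__ = [
    "MonthlyTrajectoryTable",
    "StitchedTrajectory",
    "TminMatrix",
    "GeoDistanceMatrix",
    "integrate_month",
    "precompute_monthly_tables",
    "stitch",
    "stitch_all_stations",
    "tmin_matrix",
    "overwater_distance",
]

SECONDS_PER_YEAR_FACTOR = 12  # one year = 12 model months


def _interp_uv(
    field: VelocityField, month: int, x: np.ndarray, y: np.ndarray, tfrac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear-in-space, linear-in-time velocity at positions (x, y) metres.

    Velocities live at cell centres; the two bracketing monthly snapshots
    are blended with weight ``tfrac`` (0 at the start of ``month``).
    """
    rows, cols = field.shape
    m2 = (month + 1) % field.n_months
    fx = np.clip(x / field.dx - 0.5, 0.0, cols - 1.0001)
    fy = np.clip(y / field.dy - 0.5, 0.0, rows - 1.0001)
    c0 = fx.astype(int)
    r0 = fy.astype(int)
    c1 = np.minimum(c0 + 1, cols - 1)
    r1 = np.minimum(r0 + 1, rows - 1)
    wx = fx - c0
    wy = fy - r0

    def bilin(f2d):
        return (
            f2d[r0, c0] * (1 - wy) * (1 - wx)
            + f2d[r0, c1] * (1 - wy) * wx
            + f2d[r1, c0] * wy * (1 - wx)
            + f2d[r1, c1] * wy * wx
        )

    u = (1 - tfrac) * bilin(field.u[month]) + tfrac * bilin(field.u[m2])
    v = (1 - tfrac) * bilin(field.v[month]) + tfrac * bilin(field.v[m2])
    return u, v


def _cell_of(field: VelocityField, x: np.ndarray, y: np.ndarray):
    col = np.floor(x / field.dx).astype(int)
    row = np.floor(y / field.dy).astype(int)
    return row, col


def _on_land_or_off(field: VelocityField, x, y) -> np.ndarray:
    rows, cols = field.shape
    off = (x < 0) | (x >= cols * field.dx) | (y < 0) | (y >= rows * field.dy)
    row = np.clip(np.floor(y / field.dy).astype(int), 0, rows - 1)
    col = np.clip(np.floor(x / field.dx).astype(int), 0, cols - 1)
    return off | field.landmask[row, col]


@dataclass
class MonthlyTrajectoryTable:
    """One-month float trajectories for a set of release positions."""

    month: int
    release_xy: np.ndarray  # (n, 2) metres at release
    end_xy: np.ndarray  # (n, 2) metres after one month
    end_cells: np.ndarray  # (n, 2) (row, col)
    paths: np.ndarray | None  # (n, n_stored, 2) float32, or None
    path_times: np.ndarray | None  # (n_stored,) seconds since month start
    dt: float
    K: float


def integrate_month(
    field: VelocityField,
    month: int,
    release_xy: np.ndarray,
    dt: float | None = None,
    K: float = 100.0,
    seed: int = 0,
    store_paths: bool = True,
    path_stride: int | None = None,
) -> MonthlyTrajectoryTable:
    """Advect floats for one month from the given release positions.

    Each step applies a deterministic RK4 displacement followed by a
    Gaussian diffusive kick of standard deviation ``sqrt(2 K dt)`` per
    component. A step landing on land or off-grid first reverts the kick
    and, if still invalid, reverts the whole step. Stored dense paths are
    subsampled every ``path_stride`` sub-steps (plus the endpoint).
    """
    T = field.month_length
    if dt is None:
        dt = T / 600.0
    if dt <= 0 or abs(T / dt - round(T / dt)) > 1e-9:
        raise ValueError("dt must be positive and divide the month length")
    n_steps = int(round(T / dt))
    vmax = max(np.abs(field.u).max(), np.abs(field.v).max())
    if vmax * dt > 0.5 * min(field.dx, field.dy):
        warnings.warn(
            f"CFL: max speed {vmax:.3g} m/s times dt {dt:.3g} s exceeds half "
            "a grid cell; consider a smaller dt"
        )
    if path_stride is None:
        # keep stored points closer than ~one grid cell apart
        path_stride = max(1, int(min(field.dx, field.dy) / max(vmax * dt, 1e-9)))

    rng = np.random.default_rng([seed, month])
    xy = np.asarray(release_xy, dtype=float)
    x, y = xy[:, 0].copy(), xy[:, 1].copy()
    if _on_land_or_off(field, x, y).any():
        raise ValueError("release points must be on ocean cells")
    sd = np.sqrt(2.0 * K * dt)

    stored = [np.column_stack([x, y]).astype(np.float32)]
    stored_t = [0.0]
    for step in range(n_steps):
        t0 = step * dt / T
        th = (step + 0.5) * dt / T
        t1 = (step + 1) * dt / T
        u1, v1 = _interp_uv(field, month, x, y, t0)
        u2, v2 = _interp_uv(field, month, x + 0.5 * dt * u1, y + 0.5 * dt * v1, th)
        u3, v3 = _interp_uv(field, month, x + 0.5 * dt * u2, y + 0.5 * dt * v2, th)
        u4, v4 = _interp_uv(field, month, x + dt * u3, y + dt * v3, t1)
        dx_adv = dt / 6.0 * (u1 + 2 * u2 + 2 * u3 + u4)
        dy_adv = dt / 6.0 * (v1 + 2 * v2 + 2 * v3 + v4)
        if K > 0:
            kick = rng.normal(0.0, sd, size=(2, len(x)))
        else:
            kick = np.zeros((2, len(x)))
        nx = x + dx_adv + kick[0]
        ny = y + dy_adv + kick[1]
        bad = _on_land_or_off(field, nx, ny)
        if bad.any():  # revert the stochastic kick
            nx[bad] = x[bad] + dx_adv[bad]
            ny[bad] = y[bad] + dy_adv[bad]
            still = _on_land_or_off(field, nx, ny)
            nx[still] = x[still]  # revert the whole step
            ny[still] = y[still]
        x, y = nx, ny
        if store_paths and ((step + 1) % path_stride == 0 or step == n_steps - 1):
            stored.append(np.column_stack([x, y]).astype(np.float32))
            stored_t.append((step + 1) * dt)

    row, col = _cell_of(field, x, y)
    return MonthlyTrajectoryTable(
        month=month,
        release_xy=xy,
        end_xy=np.column_stack([x, y]),
        end_cells=np.column_stack([row, col]),
        paths=np.stack(stored, axis=1) if store_paths else None,
        path_times=np.asarray(stored_t) if store_paths else None,
        dt=dt,
        K=K,
    )


def precompute_monthly_tables(
    field: VelocityField,
    dt: float | None = None,
    K: float = 100.0,
    seed: int = 0,
) -> list[MonthlyTrajectoryTable]:
    """One-month trajectories released at every ocean-cell centre, for
    every month instance in the field."""
    cells = field.ocean_cells
    release = np.column_stack(
        [(cells[:, 1] + 0.5) * field.dx, (cells[:, 0] + 0.5) * field.dy]
    )
    return [
        integrate_month(field, m, release, dt=dt, K=K, seed=seed)
        for m in range(field.n_months)
    ]


@dataclass
class StitchedTrajectory:
    """A multi-year path assembled from monthly trajectory segments."""

    release_station: str
    months: np.ndarray  # month instance per segment
    cumulative_years: float
    visits: dict[str, float]  # station_id -> first-entry time, years

    def __post_init__(self) -> None:
        cal = self.months % 12
        if len(cal) > 1 and not np.all(np.diff(cal) % 12 == 1):
            raise ValueError("month sequence must increment cyclically by 1")


class _StitchContext:
    """Dense lookup tables shared by all stitched ensembles of one field."""

    def __init__(
        self,
        field: VelocityField,
        tables: list[MonthlyTrajectoryTable],
        stations: pd.DataFrame,
        radius_cells: float,
    ):
        if len(tables) % 12 != 0 or len(tables) < 12:
            raise ValueError("monthly tables must cover all 12 calendar months")
        self.field = field
        self.stations = stations
        self.radius_m = radius_cells * min(field.dx, field.dy)
        cells = field.ocean_cells
        self.cells = cells
        rows, cols = field.shape
        idx = -np.ones((rows, cols), dtype=int)
        idx[cells[:, 0], cells[:, 1]] = np.arange(len(cells))
        self.cell_index = idx
        n_m = len(tables)
        n_c = len(cells)
        self.n_months = n_m
        self.end_idx = np.empty((n_m, n_c), dtype=np.int32)
        for m, t in enumerate(tables):
            e = idx[t.end_cells[:, 0], t.end_cells[:, 1]]
            if (e < 0).any():
                raise ValueError("a monthly trajectory ended on a land cell")
            self.end_idx[m] = e

        sx = (stations["col"].to_numpy() + 0.5) * field.dx
        sy = (stations["row"].to_numpy() + 0.5) * field.dy
        n_s = len(stations)
        self.first_entry = np.full((n_m, n_c, n_s), np.inf, dtype=np.float32)
        for m, t in enumerate(tables):
            if t.paths is None:
                raise ValueError("stitching requires dense paths to be stored")
            px = t.paths[:, :, 0]
            py = t.paths[:, :, 1]
            for s in range(n_s):
                within = (px - sx[s]) ** 2 + (py - sy[s]) ** 2 <= self.radius_m**2
                any_hit = within.any(axis=1)
                first = within.argmax(axis=1)
                entry = t.path_times[first].astype(np.float32)
                self.first_entry[m, any_hit, s] = entry[any_hit]

    def release_cells_near(self, station_row) -> np.ndarray:
        sx = (station_row["col"] + 0.5) * self.field.dx
        sy = (station_row["row"] + 0.5) * self.field.dy
        cx = (self.cells[:, 1] + 0.5) * self.field.dx
        cy = (self.cells[:, 0] + 0.5) * self.field.dy
        near = (cx - sx) ** 2 + (cy - sy) ** 2 <= self.radius_m**2
        return np.flatnonzero(near)


def _stitch_station(
    ctx: _StitchContext,
    station_row,
    n_trajectories: int,
    n_years: int,
    rng: np.random.Generator,
) -> list[StitchedTrajectory]:
    month_len = ctx.field.month_length
    n_inst = ctx.n_months
    years_of = n_inst // 12
    release = ctx.release_cells_near(station_row)
    if len(release) == 0:
        raise ValueError(f"no ocean cells within radius of {station_row['station_id']}")
    n_steps = n_years * 12
    cell = rng.choice(release, size=n_trajectories)
    minst = rng.integers(0, n_inst, size=n_trajectories)
    n_s = len(ctx.stations)
    best = np.full((n_trajectories, n_s), np.inf, dtype=np.float64)
    months_seq = np.empty((n_trajectories, n_steps), dtype=np.int32)
    for step in range(n_steps):
        months_seq[:, step] = minst
        entry = ctx.first_entry[minst, cell, :]  # (ntraj, n_s), seconds
        t_abs = step * month_len + entry
        np.minimum(best, t_abs, out=best)
        nxt_cell = ctx.end_idx[minst, cell]
        nxt_cal = (minst + 1) % 12
        year_pick = rng.integers(0, years_of, size=n_trajectories)
        minst = nxt_cal + 12 * year_pick
        cell = nxt_cell

    sec_per_year = 12 * month_len
    ids = ctx.stations["station_id"].tolist()
    out = []
    for i in range(n_trajectories):
        visits = {
            ids[s]: best[i, s] / sec_per_year
            for s in range(n_s)
            if np.isfinite(best[i, s])
        }
        out.append(
            StitchedTrajectory(
                release_station=str(station_row["station_id"]),
                months=months_seq[i],
                cumulative_years=n_steps / 12.0,
                visits=visits,
            )
        )
    return out


def stitch(
    monthly_tables: list[MonthlyTrajectoryTable],
    field: VelocityField,
    stations: pd.DataFrame,
    station_id: str,
    radius_cells: float = 2.0,
    n_trajectories: int = 100,
    n_years: int = 20,
    seed: int = 0,
) -> list[StitchedTrajectory]:
    """Stitch monthly trajectories into an ensemble for one station.

    Each trajectory starts in a uniformly chosen ocean cell within the
    capture radius of the station and a uniformly chosen starting month
    instance; at every month boundary it continues with a stored
    trajectory of the following calendar month (any available year,
    chosen uniformly) starting in its current end cell.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    ctx = _StitchContext(field, monthly_tables, stations, radius_cells)
    row = stations.loc[stations["station_id"] == station_id].iloc[0]
    rng = np.random.default_rng([seed, int(row.name)])
    return _stitch_station(ctx, row, n_trajectories, n_years, rng)


def stitch_all_stations(
    monthly_tables: list[MonthlyTrajectoryTable],
    field: VelocityField,
    stations: pd.DataFrame,
    radius_cells: float = 2.0,
    n_trajectories: int = 100,
    n_years: int = 20,
    seed: int = 0,
) -> dict[str, list[StitchedTrajectory]]:
    """Stitched ensembles for every station, sharing the lookup tables."""
    ctx = _StitchContext(field, monthly_tables, stations, radius_cells)
    out = {}
    for pos, (_, row) in enumerate(stations.iterrows()):
        rng = np.random.default_rng([seed, pos])
        out[str(row["station_id"])] = _stitch_station(
            ctx, row, n_trajectories, n_years, rng
        )
    return out


@dataclass
class TminMatrix:
    """Directed minimum travel times (years) with connection counts."""

    ids: list[str]
    tmin: np.ndarray  # (n, n) years; NaN where no connection
    counts: np.ndarray  # (n, n) number of connecting trajectories
    min_connections: int

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.tmin) & (self.counts > self.min_connections)

    def symmetrized(self) -> np.ndarray:
        """Elementwise minimum of the two directions over valid entries."""
        t = np.where(self.valid, self.tmin, np.inf)
        sym = np.minimum(t, t.T)
        sym[np.isinf(sym)] = np.nan
        np.fill_diagonal(sym, 0.0)
        return sym


def tmin_matrix(
    trajectory_sets: dict[str, list[StitchedTrajectory]],
    stations: pd.DataFrame,
    min_connections: int = 0,
    close_paths: bool = True,
) -> TminMatrix:
    """Directed T_min over trajectory ensembles.

    ``T_min[i, j]`` is the minimum first-entry time at station j over all
    trajectories released near station i; the pair is masked invalid when
    the number of connecting trajectories is <= ``min_connections``.

    With ``close_paths`` (default) the matrix is additionally closed
    under path concatenation (min-plus transitive closure over valid
    pairs): a trajectory reaching k in ``T[i, k]`` continued by one
    reaching j in ``T[k, j]`` witnesses a connection in their sum. An
    exhaustive ensemble is closed automatically (any concatenation is
    itself a stitchable trajectory); applying the closure removes the
    finite-ensemble overestimation of rarely sampled pairs.
    """
    ids = stations["station_id"].tolist()
    n = len(ids)
    pos = {s: i for i, s in enumerate(ids)}
    tmin = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    for sid, trajs in trajectory_sets.items():
        i = pos[sid]
        for tr in trajs:
            for other, t in tr.visits.items():
                j = pos[other]
                counts[i, j] += 1
                if not np.isfinite(tmin[i, j]) or t < tmin[i, j]:
                    tmin[i, j] = t
    np.fill_diagonal(tmin, 0.0)
    if close_paths:
        t = np.where(np.isfinite(tmin) & (counts > min_connections), tmin, np.inf)
        np.fill_diagonal(t, 0.0)
        for k in range(n):
            t = np.minimum(t, t[:, k, None] + t[None, k, :])
        closed = np.isfinite(t)
        tmin = np.where(closed, t, np.nan)
        # a closed pair is supported by at least the weakest of its links
        counts = np.where(
            closed & ~(counts > min_connections), min_connections + 1, counts
        )
        np.fill_diagonal(tmin, 0.0)
    return TminMatrix(ids=ids, tmin=tmin, counts=counts, min_connections=min_connections)


@dataclass
class GeoDistanceMatrix:
    """Shortest over-water distances between stations, km."""

    ids: list[str]
    values_km: np.ndarray


def overwater_distance(
    stations: pd.DataFrame, landmask: np.ndarray, dx_km: float, dy_km: float
) -> GeoDistanceMatrix:
    """Shortest path between stations on the 8-neighbour ocean-cell graph.

    Edge weights are centre-to-centre distances in km; pairs in
    disconnected ocean components get NaN.
    """
    landmask = np.asarray(landmask, dtype=bool)
    rows, cols = landmask.shape
    cells = np.argwhere(~landmask)
    idx = -np.ones((rows, cols), dtype=int)
    idx[cells[:, 0], cells[:, 1]] = np.arange(len(cells))
    st_cells = stations[["row", "col"]].to_numpy()
    if landmask[st_cells[:, 0], st_cells[:, 1]].any():
        raise ValueError("stations must be on ocean cells")

    src_l, dst_l, w_l = [], [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r2 = cells[:, 0] + dr
            c2 = cells[:, 1] + dc
            ok = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
            ok[ok] &= ~landmask[r2[ok], c2[ok]]
            src_l.append(idx[cells[ok, 0], cells[ok, 1]])
            dst_l.append(idx[r2[ok], c2[ok]])
            w_l.append(
                np.full(ok.sum(), float(np.hypot(dr * dy_km, dc * dx_km)))
            )
    g = csr_matrix(
        (np.concatenate(w_l), (np.concatenate(src_l), np.concatenate(dst_l))),
        shape=(len(cells), len(cells)),
    )
    st_idx = idx[st_cells[:, 0], st_cells[:, 1]]
    dist = dijkstra(g, indices=st_idx)[:, st_idx]
    dist[np.isinf(dist)] = np.nan
    np.fill_diagonal(dist, 0.0)
    return GeoDistanceMatrix(
        ids=stations["station_id"].tolist(), values_km=dist
    )
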