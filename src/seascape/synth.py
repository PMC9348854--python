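"""Synthetic toy ocean: velocity field, stations, communities, reads, environment.

This module generates a fully synthetic seascape carrying the statistical
structure the downstream analysis assumes, so that every stage of the
pipeline can be exercised without any external data:

* a seasonal double-gyre velocity field on a masked Cartesian grid, with
  two basins separated by a barrier pierced by a channel jet;
* stations placed on energetic streamlines of the mean flow, with a
  generator-known basin truth label;
* station communities drawn from a latent-Gaussian threshold model whose
  expected presence/absence Jaccard similarity decays exponentially with
  along-current travel time at a designed e-folding rate ``tau_true``;
* shotgun-like reads drawn from per-taxon synthetic genomes with uniform
  substitution errors;
* environmental fields (latitudinal temperature gradient, nutrients
  decaying away from upwelling sources along the mean flow, lognormal
  chlorophyll and surface PAR).

All operations are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import norm

from .field import MONTH_LENGTH_S, VelocityField

__all__ = [
    "CommunityTable",
    "TaxonGenomes",
    "ReadSet",
    "make_velocity_field",
    "place_stations",
    "simulate_communities",
    "make_genomes",
    "emit_reads",
    "emit_env",
    "DEFAULT_OCCUPANCY",
]

#: Expected per-taxon presence probability (community richness per station).
DEFAULT_OCCUPANCY = 0.22

#: Expected Jaccard similarity between two stations separated by vanishing
#: travel time: the local-patchiness floor (communities differ even between
#: adjacent sites).
DEFAULT_BASELINE_SIMILARITY = 0.45

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# velocity field
# ---------------------------------------------------------------------------

def make_velocity_field(
    grid_rows: int = 64,
    grid_cols: int = 128,
    n_months: int = 24,
    seasonal_amplitude: float = 0.4,
    seed: int = 0,
    dx: float = 18_000.0,
    dy: float = 18_000.0,
    target_speed: float = 0.15,
    month_length: float = MONTH_LENGTH_S,
) -> VelocityField:
    """Build a seasonal two-gyre toy velocity field.

    The flow derives from a streamfunction psi (u = -dpsi/dy, v = dpsi/dx,
    central differences), so it is non-divergent on interior ocean cells.
    The domain has a one-cell land frame and a mid-domain meridional
    barrier with a gap through which a localized jet connects the two
    counter-rotating basin gyres. Monthly fields are the streamfunction
    scaled by ``1 + seasonal_amplitude * cos(2 pi month / 12)``.

    Parameters
    ----------
    target_speed : float
        Approximate maximum gyre speed, m/s (the streamfunction is scaled
        to reach it).
    """
    if grid_rows < 16 or grid_cols < 16:
        raise ValueError(
            "grid too small to host two gyres: need grid_rows, grid_cols >= 16"
        )
    if n_months < 12 or n_months % 12 != 0:
        raise ValueError("n_months must be a positive multiple of 12")

    rows, cols = grid_rows, grid_cols
    # land frame + meridional barrier with a gap
    landmask = np.zeros((rows, cols), dtype=bool)
    landmask[0, :] = landmask[-1, :] = True
    landmask[:, 0] = landmask[:, -1] = True
    c_bar = cols // 2
    gap_half = max(2, rows // 10)
    gap_lo, gap_hi = rows // 2 - gap_half, rows // 2 + gap_half
    landmask[:, c_bar] = True
    landmask[gap_lo:gap_hi, c_bar] = False

    yy, xx = np.mgrid[0:rows, 0:cols]
    xt = xx / (cols - 1)
    yt = yy / (rows - 1)

    # two counter-rotating gyres; psi = 0 along the barrier line
    psi_gyre = np.sin(2 * np.pi * xt) * np.sin(np.pi * yt)
    # localized jet pumping water eastward through the gap
    ramp = np.clip((yy - gap_lo) / max(gap_hi - gap_lo - 1, 1), 0.0, 1.0)
    bump = np.exp(-(((xt - 0.5) / 0.12) ** 2))
    psi_jet = -0.6 * ramp * bump
    psi = psi_gyre + psi_jet

    # scale streamfunction so peak speed is ~target_speed
    u0 = -(np.roll(psi, -1, axis=0) - np.roll(psi, 1, axis=0)) / (2 * dy)
    v0 = (np.roll(psi, -1, axis=1) - np.roll(psi, 1, axis=1)) / (2 * dx)
    speed = np.hypot(u0, v0)[~landmask].max()
    psi *= target_speed / speed

    months = np.arange(n_months)
    season = 1.0 + seasonal_amplitude * np.cos(2 * np.pi * (months % 12) / 12.0)
    u = np.empty((n_months, rows, cols))
    v = np.empty((n_months, rows, cols))
    for m in months:
        pm = psi * season[m]
        u[m] = -(np.roll(pm, -1, axis=0) - np.roll(pm, 1, axis=0)) / (2 * dy)
        v[m] = (np.roll(pm, -1, axis=1) - np.roll(pm, 1, axis=1)) / (2 * dx)
        u[m][landmask] = 0.0
        v[m][landmask] = 0.0

    return VelocityField(
        u=u, v=v, dx=dx, dy=dy, landmask=landmask, month_length=month_length
    )


def basin_of(field: VelocityField, row, col) -> np.ndarray:
    """Truth basin label ('A' west of the barrier, 'B' east) per cell."""
    c_bar = field.shape[1] // 2
    return np.where(np.asarray(col) < c_bar, "A", "B")


# ---------------------------------------------------------------------------
# stations
# ---------------------------------------------------------------------------

def place_stations(
    field: VelocityField,
    n_stations: int = 20,
    seed: int = 0,
    speed_quantile: float = 0.75,
    min_separation_cells: float = 5.0,
    barrier_buffer_cells: int = 8,
) -> pd.DataFrame:
    """Place stations on energetic ocean cells, both basins represented.

    Stations are sampled (seeded) from ocean cells whose mean-flow speed
    exceeds the ``speed_quantile`` quantile, with a minimum pairwise
    separation, split evenly between the two basins. Returns a station
    table with one row per station: grid position, nominal lon/lat,
    sampling month, depth layer, basin truth label, and exclusion flags.
    """
    if n_stations < 6:
        raise ValueError("n_stations must be >= 6")
    rng = np.random.default_rng(seed)
    um, vm = field.mean_field()
    speed = np.hypot(um, vm)
    ocean = ~field.landmask
    if n_stations > ocean.sum():
        raise ValueError("n_stations exceeds the number of distinct ocean cells")
    thresh = np.quantile(speed[ocean], speed_quantile)

    c_bar = field.shape[1] // 2
    rows_cols = np.argwhere(ocean & (speed >= thresh))
    # keep stations out of the connecting channel so each lies in a gyre core
    away = np.abs(rows_cols[:, 1] - c_bar) >= barrier_buffer_cells
    rows_cols = rows_cols[away]
    west = rows_cols[rows_cols[:, 1] < c_bar]
    east = rows_cols[rows_cols[:, 1] >= c_bar]
    n_west = n_stations // 2
    quotas = [(west, n_west), (east, n_stations - n_west)]

    chosen: list[np.ndarray] = []
    for pool, quota in quotas:
        pool = pool[rng.permutation(len(pool))]
        picked = 0
        for cell in pool:
            if picked == quota:
                break
            if all(
                np.hypot(*(cell - c)) >= min_separation_cells for c in chosen
            ):
                chosen.append(cell)
                picked += 1
        if picked < quota:
            raise ValueError(
                "could not place the requested number of stations; "
                "lower min_separation_cells or speed_quantile"
            )

    cells = np.array(chosen)
    order = np.lexsort((cells[:, 1], cells[:, 0]))
    cells = cells[order]
    n = len(cells)
    table = pd.DataFrame(
        {
            "station_id": [f"S{i + 1:02d}" for i in range(n)],
            "row": cells[:, 0],
            "col": cells[:, 1],
            # nominal flat projection: 1 degree per 111.32 km
            "lon": cells[:, 1] * field.dx / 111_320.0,
            "lat": cells[:, 0] * field.dy / 111_320.0,
            "depth_layer": "surface",
            "sampling_month": rng.integers(1, 13, size=n),
            "basin": basin_of(field, cells[:, 0], cells[:, 1]),
            "coastal": False,
            "southern_ocean": False,
        }
    )
    return table


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

from functools import lru_cache

from scipy.stats import multivariate_normal


@lru_cache(maxsize=8)
def _jaccard_curve(occupancy: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Expected Jaccard similarity of the threshold model vs latent
    correlation, tabulated on a grid for numerical inversion."""
    c = norm.ppf(1.0 - occupancy)
    rhos = np.concatenate([np.linspace(-0.95, 0.98, 120), np.linspace(0.981, 1.0, 40)])
    js = []
    for r in rhos:
        if r >= 1.0:
            p11 = occupancy
        else:
            mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
            p11 = float(mvn.cdf([-c, -c]))  # = P(z1 > c, z2 > c) by symmetry
        js.append(p11 / (2 * occupancy - p11))
    return tuple(rhos), tuple(js)


def _latent_corr_for_jaccard(target_j: np.ndarray, occupancy: float) -> np.ndarray:
    """Latent correlations giving the target expected Jaccard similarities."""
    rhos, js = _jaccard_curve(round(float(occupancy), 6))
    return np.interp(target_j, np.asarray(js), np.asarray(rhos))

@dataclass
class CommunityTable:
    """Presence/abundance of taxa per station plus the generator truth."""

    presence: pd.DataFrame  # stations x taxa, 0/1
    abundance: pd.DataFrame  # stations x taxa, >= 0
    tau_true: float
    basins: pd.Series  # station -> basin label
    occupancy: float

    def __post_init__(self) -> None:
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if (self.presence.sum(axis=1) < 1).any():
            raise ValueError("every station must have at least one taxon present")


def simulate_communities(
    stations: pd.DataFrame,
    tmin_sym: np.ndarray,
    tau_true: float = 1.0,
    n_taxa: int = 2000,
    basin_pool_divergence: float = 1.0,
    seed: int = 0,
    occupancy: float = DEFAULT_OCCUPANCY,
    baseline_similarity: float = DEFAULT_BASELINE_SIMILARITY,
    cross_basin_time: float | None = None,
    saturation_time: float | None = None,
) -> CommunityTable:
    """Draw station communities whose similarity decays with travel time.

    For each taxon a latent Gaussian field over stations is drawn and
    thresholded to presence at the ``occupancy`` quantile. The latent
    correlation between two stations is chosen (by numerically inverting
    the Jaccard-vs-correlation curve of the threshold model) so that the
    expected presence/absence Jaccard similarity equals
    ``baseline_similarity * exp(-T_eff / tau_true)``: an exact
    exponential decay with e-folding time ``tau_true`` on top of a
    local-patchiness floor. Stations with exactly zero travel time (the
    same water parcel) get perfectly correlated latent fields and hence
    identical communities.

    ``T_eff`` equals the symmetrized travel time for within-basin pairs,
    saturated at ``saturation_time`` (default ``1.5 * tau_true``):
    recirculation within a gyre keeps same-basin communities from
    decorrelating completely. Between-basin pairs use a large constant
    (default ``3 * tau_true``) plus an offset ``5 * tau_true *
    basin_pool_divergence``; the divergence additionally anti-correlates
    the basins' latent fields (``-0.35 * min(divergence, 1)``), encoding
    basin-specific taxon pools (taxa common in one basin and rare in the
    other).
    """
    if tau_true <= 0:
        raise ValueError("tau_true must be positive")
    T = np.asarray(tmin_sym, dtype=float)
    n = len(stations)
    if T.shape != (n, n):
        raise ValueError("tmin_sym shape does not match the station table")
    if not np.allclose(T, T.T, equal_nan=True):
        raise ValueError("tmin_sym must be symmetric")
    if np.nanmin(T) < 0:
        raise ValueError("travel times must be non-negative")

    basins = stations["basin"].to_numpy()
    same = basins[:, None] == basins[None, :]
    T = np.where(np.isnan(T), np.inf, T)
    if cross_basin_time is None:
        cross_basin_time = 3.0 * tau_true
    if saturation_time is None:
        saturation_time = 1.5 * tau_true
    T_eff = np.where(
        same,
        np.minimum(T, saturation_time),
        cross_basin_time + 5.0 * tau_true * basin_pool_divergence,
    )
    np.fill_diagonal(T_eff, 0.0)

    target_j = baseline_similarity * np.exp(-T_eff / tau_true)
    C = _latent_corr_for_jaccard(target_j, occupancy)
    # Between-basin pools are anti-correlated (taxa favoured in one basin,
    # rare in the other) but floored at -0.35: stronger anti-correlation is
    # infeasible jointly with the within-basin coherence structure.
    C[~same] = np.maximum(C[~same], -0.35)
    # zero travel time = the same water parcel: identical communities
    C[(T_eff == 0.0) & same] = 1.0
    w, V = np.linalg.eigh(C)
    # Exp(-T) of an empirical (non-metric) travel-time matrix can carry
    # modest negative eigenvalues; project onto the PSD cone and restore
    # unit latent variances. Gross violations indicate inconsistent input.
    if w.min() < -0.25 * w.max():
        raise ValueError("covariance not positive semi-definite after jitter")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    L /= np.linalg.norm(L, axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    latent = L @ rng.standard_normal((n, n_taxa))
    cutoff = norm.ppf(1.0 - occupancy)
    presence = latent > cutoff
    # guarantee at least one taxon per station
    empty = ~presence.any(axis=1)
    if empty.any():
        presence[empty, latent[empty].argmax(axis=1)] = True

    # abundance: lognormal mass for present taxa
    mass = np.exp(rng.standard_normal((n, n_taxa)))
    abundance = np.where(presence, mass, 0.0)

    taxa = [f"T{j + 1:04d}" for j in range(n_taxa)]
    ids = stations["station_id"].tolist()
    return CommunityTable(
        presence=pd.DataFrame(presence.astype(int), index=ids, columns=taxa),
        abundance=pd.DataFrame(abundance, index=ids, columns=taxa),
        tau_true=float(tau_true),
        basins=pd.Series(basins, index=ids),
        occupancy=float(occupancy),
    )


# ---------------------------------------------------------------------------
# genomes and reads
# ---------------------------------------------------------------------------

@dataclass
class TaxonGenomes:
    """Per-taxon random nucleotide sequences, all of equal length."""

    codes: np.ndarray  # (n_taxa, L) uint8 in 0..3
    taxa: list[str]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, i: int) -> str:
        return _BASES[self.codes[i]].tobytes().decode("ascii")


def make_genomes(n_taxa: int = 2000, length: int = 2000, seed: int = 0) -> TaxonGenomes:
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n_taxa, length), dtype=np.uint8)
    return TaxonGenomes(codes=codes, taxa=[f"T{j + 1:04d}" for j in range(n_taxa)])


@dataclass
class ReadSet:
    """An ordered collection of same-length reads for one sample.

    The order is stable: subsampling always takes a prefix.
    """

    sample_id: str
    reads: list[str]
    read_length: int

    def __post_init__(self) -> None:
        if any(len(r) == 0 for r in self.reads):
            raise ValueError("reads must be non-empty")

    def __len__(self) -> int:
        return len(self.reads)


def emit_reads(
    communities: CommunityTable,
    genomes: TaxonGenomes,
    reads_per_sample: int = 20_000,
    read_length: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
) -> dict[str, ReadSet]:
    """Draw shotgun-like reads for every station.

    Reads are sampled from the genomes of present taxa with probability
    proportional to abundance, with uniform start positions and per-base
    substitution errors at ``error_rate``.
    """
    if reads_per_sample < 1000:
        raise ValueError("reads_per_sample must be >= 1000")
    if not (0 <= error_rate < 0.1):
        raise ValueError("error_rate must lie in [0, 0.1)")
    if read_length > genomes.length:
        raise ValueError("read_length exceeds the genome length")

    out: dict[str, ReadSet] = {}
    abundance = communities.abundance
    for s_idx, sid in enumerate(abundance.index):
        rng = np.random.default_rng([seed, s_idx])
        weights = abundance.iloc[s_idx].to_numpy(dtype=float)
        probs = weights / weights.sum()
        taxa = rng.choice(len(probs), size=reads_per_sample, p=probs)
        starts = rng.integers(0, genomes.length - read_length + 1, size=reads_per_sample)
        window = starts[:, None] + np.arange(read_length)[None, :]
        codes = genomes.codes[taxa[:, None], window]
        if error_rate > 0:
            err = rng.random(codes.shape) < error_rate
            shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
            codes = np.where(err, (codes + shift) % 4, codes).astype(np.uint8)
        chars = _BASES[codes]
        reads = [chars[i].tobytes().decode("ascii") for i in range(reads_per_sample)]
        out[sid] = ReadSet(sample_id=sid, reads=reads, read_length=read_length)
    return out


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def _flow_time_from(
    field: VelocityField, sources: np.ndarray, floor_speed: float = 0.01
) -> np.ndarray:
    """Approximate along-mean-flow travel time (s) from source cells.

    Shortest path on the 8-neighbor ocean graph with edge weight
    distance / mean local speed (floored), a cheap proxy for advection
    time used only to shape the synthetic nutrient fields.
    """
    rows, cols = field.shape
    ocean = ~field.landmask
    idx = -np.ones((rows, cols), dtype=int)
    cells = np.argwhere(ocean)
    idx[cells[:, 0], cells[:, 1]] = np.arange(len(cells))
    um, vm = field.mean_field()
    speed = np.maximum(np.hypot(um, vm), floor_speed)

    rows_i, cols_i, data = [], [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r2 = cells[:, 0] + dr
            c2 = cells[:, 1] + dc
            ok = (0 <= r2) & (r2 < rows) & (0 <= c2) & (c2 < cols)
            ok &= ocean[r2 % rows, c2 % cols] & ok
            src = idx[cells[ok, 0], cells[ok, 1]]
            dst = idx[r2[ok], c2[ok]]
            dist = np.hypot(dr * field.dy, dc * field.dx)
            pair_speed = (
                speed[cells[ok, 0], cells[ok, 1]] + speed[r2[ok], c2[ok]]
            ) / 2.0
            rows_i.append(src)
            cols_i.append(dst)
            data.append(dist / pair_speed)
    g = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(len(cells), len(cells)),
    )
    src_idx = idx[sources[:, 0], sources[:, 1]]
    if (src_idx < 0).any():
        raise ValueError("upwelling cells must be ocean cells")
    t = dijkstra(g, indices=src_idx, min_only=True)
    out = np.full((rows, cols), np.inf)
    out[cells[:, 0], cells[:, 1]] = t
    return out


def emit_env(
    stations: pd.DataFrame,
    field: VelocityField,
    upwelling_cells: np.ndarray | None = None,
    seed: int = 0,
    noise: float = 0.05,
) -> pd.DataFrame:
    """Generate per-station, per-month environmental parameters.

    Temperature follows a latitudinal gradient plus a seasonal sinusoid;
    NO3+NO2, PO4, and Fe decay exponentially with along-mean-flow travel
    time from upwelling source cells (multiplicative lognormal noise);
    chlorophyll and surface PAR are positive lognormal covariates.
    Returns a long table (station_id, month, parameter columns).
    """
    rng = np.random.default_rng(seed)
    rows = field.shape[0]
    if upwelling_cells is None:
        # default: one upwelling source in each basin's eastern boundary
        ocean_cells = field.ocean_cells
        c_bar = field.shape[1] // 2
        picks = []
        for lo, hi in ((1, c_bar), (c_bar, field.shape[1] - 1)):
            sub = ocean_cells[(ocean_cells[:, 1] >= lo) & (ocean_cells[:, 1] < hi)]
            picks.append(sub[np.argmax(sub[:, 1] + 0.001 * sub[:, 0])])
        upwelling_cells = np.array(picks)
    upwelling_cells = np.asarray(upwelling_cells)
    if field.landmask[upwelling_cells[:, 0], upwelling_cells[:, 1]].any():
        raise ValueError("upwelling cells must be ocean cells")

    t_flow = _flow_time_from(field, upwelling_cells)  # seconds
    t_flow_yr = t_flow / (12 * field.month_length)
    decay = 0.5  # years; nutrient relaxation time along the flow

    records = []
    nutrient_scales = {"no3_no2": 8.0, "po4": 0.5, "fe": 1.2e-3}
    for _, st in stations.iterrows():
        r, c = int(st["row"]), int(st["col"])
        lat_frac = r / (rows - 1)
        t_yr = t_flow_yr[r, c]
        base = {
            name: scale * np.exp(-t_yr / decay)
            for name, scale in nutrient_scales.items()
        }
        chl = float(np.exp(rng.normal(np.log(0.3), 0.6)))
        par0 = float(np.exp(rng.normal(np.log(35.0), 0.3)))
        for month in range(1, 13):
            temp = (
                28.0
                - 18.0 * lat_frac
                + 3.0 * np.cos(2 * np.pi * (month - 1) / 12.0)
                + (rng.normal(0.0, noise) if noise > 0 else 0.0)
            )
            nut = {
                k: v * (np.exp(rng.normal(0.0, noise)) if noise > 0 else 1.0)
                for k, v in base.items()
            }
            records.append(
                {
                    "station_id": st["station_id"],
                    "month": month,
                    "temperature": temp,
                    **nut,
                    "chlorophyll": chl,
                    "par0": par0,
                    "day_length": 12.0
                    - 3.0
                    * (lat_frac - 0.5)
                    * np.cos(2 * np.pi * (month - 1) / 12.0),
                }
            )
    return pd.DataFrame.from_records(records)


def env_at_sampling(env: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """One row per station: environment at its sampling month."""
    merged = env.merge(
        stations[["station_id", "sampling_month"]],
        left_on=["station_id", "month"],
        right_on=["station_id", "sampling_month"],
    )
    return merged.drop(columns=["month", "sampling_month"]).set_index("station_id")
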