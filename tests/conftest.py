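"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import seascape as ss
from seascape.pipeline import stage_seed

GSEED = 1  # global seed for the reference toy seascape


@pytest.fixture(scope="session")
def small_field():
    """A quick 32x64 single-year field for transport unit tests."""
    return ss.make_velocity_field(32, 64, 12, seasonal_amplitude=0.4, seed=7)


@pytest.fixture(scope="session")
def toy_seascape():
    """The documented-default synthetic seascape, built once per session.

    64x128 grid, 24 months, 20 stations, 100 trajectories x 20 years per
    station, capture radius 2 cells, eddy diffusivity 100 m^2/s.
    """
    field = ss.make_velocity_field(64, 128, 24, seed=stage_seed(GSEED, "field"))
    stations = ss.place_stations(field, 20, seed=stage_seed(GSEED, "stations"))
    tables = ss.precompute_monthly_tables(
        field, dt=field.month_length / 300, K=100.0, seed=stage_seed(GSEED, "transport")
    )
    ensembles = ss.stitch_all_stations(
        tables,
        field,
        stations,
        radius_cells=2.0,
        n_trajectories=100,
        n_years=20,
        seed=stage_seed(GSEED, "stitch"),
    )
    tmin = ss.tmin_matrix(ensembles, stations, min_connections=5)
    return {
        "field": field,
        "stations": stations,
        "tables": tables,
        "ensembles": ensembles,
        "tmin": tmin,
        "tsym": tmin.symmetrized(),
    }


@pytest.fixture(scope="session")
def toy_communities(toy_seascape):
    """Reference communities with tau_true = 1 year on the toy seascape."""
    return ss.simulate_communities(
        toy_seascape["stations"],
        toy_seascape["tsym"],
        tau_true=1.0,
        n_taxa=2000,
        seed=stage_seed(GSEED, "comm0"),
    )


def random_dissimilarity(n: int, rng: np.random.Generator, scale: float = 100.0):
    """A valid random DissimilarityMatrix (symmetric, zero diagonal)."""
    v = rng.uniform(0, scale, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return ss.DissimilarityMatrix(
        ids=[f"S{i}" for i in range(n)], values=v, metric="test"
    )
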