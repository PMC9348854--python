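"""Distance-matrix correlations, turnover fit, ANOSIM, environmental stats."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from seascape.stats import (
    anosim,
    cumulative_correlation,
    env_distance,
    mantel,
    nutrient_ratio,
    par_at_depth,
    partial_spearman,
    seasonality_index,
    spearman,
    turnover_fit,
    turnover_fit_from_matrices,
)

from conftest import random_dissimilarity


# ---------------------------------------------------------------------------
# environmental distances and indices
# ---------------------------------------------------------------------------

def test_env_distance_identical_stations_are_zero():
    env = pd.DataFrame({"t": [5.0, 5.0], "n": [1.0, 1.0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="zero variance"):
        env_distance(env, ["t", "n"])
    env2 = pd.DataFrame({"t": [5.0, 5.0, 7.0]}, index=["a", "b", "c"])
    d = env_distance(env2, ["t"])
    assert d.values[0, 1] == 0.0


def test_env_distance_single_parameter_equals_zscore_gap():
    env = pd.DataFrame({"t": [0.0, 2.0]}, index=["a", "b"])
    d = env_distance(env, ["t"])
    z = (np.array([0, 2.0]) - 1.0) / 1.0  # population sd = 1
    assert d.values[0, 1] == pytest.approx(abs(z[0] - z[1]), abs=1e-12)


def test_env_distance_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    env = pd.DataFrame(
        rng.normal(size=(6, 4)), index=[f"s{i}" for i in range(6)],
        columns=list("wxyz"),
    )
    d = env_distance(env, list("wxyz"))
    X = env.to_numpy()
    Z = (X - X.mean(0)) / X.std(0)
    for i in range(6):
        for j in range(6):
            expected = np.sqrt(((Z[i] - Z[j]) ** 2).sum())
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_nutrient_ratio_floors_zero_denominator():
    num = pd.Series([4.0, 2.0])
    den = pd.Series([2.0, 0.0])
    r = nutrient_ratio(num, den, zero_floor=1e-6)
    assert r[0] == 2.0
    assert r[1] == pytest.approx(2.0 / 1e-6)


def test_par_at_depth_surface_reference_and_attenuation():
    assert par_at_depth(30.0, 0.5, 0.0) == pytest.approx(30.0)
    # at the derived reference depth PAR is exactly 1% of the surface value
    x = np.log10(0.5)
    Z = 10 ** (1.524 - 0.426 * x - 0.0145 * x**2 + 0.0186 * x**3)
    assert par_at_depth(30.0, 0.5, Z) == pytest.approx(0.3)


def test_par_at_depth_chl_one_reference_values():
    # x = 0: Z = 10^1.524 = 33.42 m, k = -ln(0.01)/Z = 0.1378 1/m
    Z = 10**1.524
    assert Z == pytest.approx(33.42, abs=0.01)
    k = -np.log(0.01) / Z
    assert k == pytest.approx(0.1378, abs=0.0002)
    assert par_at_depth(1.0, 1.0, 10.0) == pytest.approx(np.exp(-k * 10.0), rel=1e-12)
    with pytest.raises(ValueError, match="chlorophyll"):
        par_at_depth(30.0, 0.0, 5.0)


def test_seasonality_index_ranges():
    table = pd.DataFrame(
        {m: [np.sin(m / 12 * 2 * np.pi) * a for a in (1.0, 2.0, 0.0)] for m in range(12)},
        index=["half", "top", "flat"],
    )
    si = seasonality_index(table)
    assert si["top"] == 1.0
    assert si["half"] == pytest.approx(0.5)
    assert si["flat"] == 0.0
    with pytest.raises(ValueError):
        seasonality_index(table.loc[["flat"]])


# ---------------------------------------------------------------------------
# Spearman / Mantel / partial
# ---------------------------------------------------------------------------

def masked_spearman_oracle(V1, V2, mask=None):
    n = V1.shape[0]
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if mask is None or mask[i, j]:
                xs.append(V1[i, j])
                ys.append(V2[i, j])
    rx, ry = rankdata(xs), rankdata(ys)
    return np.corrcoef(rx, ry)[0, 1]


def test_spearman_self_and_monotone_transform_give_one():
    rng = np.random.default_rng(1)
    D = random_dissimilarity(7, rng)
    assert spearman(D, D) == pytest.approx(1.0)
    transformed = np.exp(D.values / 40.0)
    np.fill_diagonal(transformed, 0.0)
    assert spearman(D, transformed) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_spearman_matches_rank_pearson_oracle_with_mask(seed):
    rng = np.random.default_rng(seed)
    D1 = random_dissimilarity(8, rng)
    D2 = random_dissimilarity(8, rng)
    mask = rng.random((8, 8)) < 0.7
    mask = mask | mask.T
    assert spearman(D1, D2, mask) == pytest.approx(
        masked_spearman_oracle(D1.values, D2.values, mask), abs=1e-12
    )


def test_spearman_needs_three_pairs():
    D = random_dissimilarity(3, np.random.default_rng(0))
    mask = np.zeros((3, 3), dtype=bool)
    mask[0, 1] = mask[1, 0] = True
    assert np.isnan(spearman(D, D, mask))


def test_mantel_identity_gives_minimal_p():
    rng = np.random.default_rng(2)
    D = random_dissimilarity(10, rng)
    rho, p = mantel(D, D, n_perm=999, seed=0)
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(1 / 1000)


def test_mantel_is_seed_deterministic():
    rng = np.random.default_rng(3)
    D1 = random_dissimilarity(9, rng)
    D2 = random_dissimilarity(9, rng)
    assert mantel(D1, D2, n_perm=199, seed=7) == mantel(D1, D2, n_perm=199, seed=7)


def test_partial_spearman_reduces_and_rejects():
    rng = np.random.default_rng(4)
    D1 = random_dissimilarity(8, rng)
    D2 = random_dissimilarity(8, rng)
    D3 = random_dissimilarity(8, rng)
    r12 = spearman(D1, D2)
    r13 = spearman(D1, D3)
    r23 = spearman(D2, D3)
    expected = (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))
    assert partial_spearman(D1, D2, D3) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError, match="perfectly"):
        partial_spearman(D1, D1, D1)


def test_matrix_correlations_invariant_to_station_reordering():
    rng = np.random.default_rng(5)
    D1 = random_dissimilarity(8, rng)
    D2 = random_dissimilarity(8, rng)
    perm = rng.permutation(8)
    P1 = D1.values[np.ix_(perm, perm)]
    P2 = D2.values[np.ix_(perm, perm)]
    assert spearman(P1, P2) == pytest.approx(spearman(D1, D2), abs=1e-12)


# ---------------------------------------------------------------------------
# cumulative correlation
# ---------------------------------------------------------------------------

def test_cumulative_correlation_endpoints():
    rng = np.random.default_rng(6)
    D = random_dissimilarity(9, rng)
    T = random_dissimilarity(9, rng, scale=3.0).values
    thr = np.array([0.001, 10.0])
    curve = cumulative_correlation(D, T, thr, min_pairs=3)
    assert np.isnan(curve.rho[0])  # below the smallest T: empty mask
    assert curve.rho[1] == pytest.approx(spearman(D, T), abs=1e-12)
    assert (np.diff(curve.n_pairs) >= 0).all()


def test_cumulative_correlation_piecewise_constant_between_t_values():
    rng = np.random.default_rng(7)
    D = random_dissimilarity(8, rng)
    T = random_dissimilarity(8, rng, scale=2.0).values
    iu = np.triu_indices(8, 1)
    ts = np.sort(T[iu])
    mid1 = (ts[10] + ts[11]) / 2
    mid2 = ts[11] - 1e-9  # still below the 12th value
    curve = cumulative_correlation(D, T, np.array([mid1, mid2]), min_pairs=3)
    assert curve.rho[0] == pytest.approx(curve.rho[1], abs=1e-12)


def test_cumulative_correlation_bootstrap_ci_brackets_rho():
    rng = np.random.default_rng(8)
    base = np.abs(rng.normal(size=(12, 12)))
    T = (base + base.T) / 2
    np.fill_diagonal(T, 0)
    D = T * 30 + rng.normal(scale=1.0, size=T.shape)
    D = (D + D.T) / 2
    D = D - D.min() + 1
    np.fill_diagonal(D, 0)
    curve = cumulative_correlation(D, T, np.array([T.max() + 1]), min_pairs=5,
                                   n_boot=100, seed=1)
    assert curve.ci_lo[0] <= curve.rho[0] <= curve.ci_hi[0]


# ---------------------------------------------------------------------------
# turnover fit
# ---------------------------------------------------------------------------

def test_turnover_fit_recovers_noiseless_exponential():
    x = np.linspace(0.05, 1.4, 20)
    y = 80 * np.exp(-x / 1.2)
    fit = turnover_fit(y, x, t_max=1.5)
    assert fit.c0 == pytest.approx(80.0, abs=1e-6)
    assert fit.tau == pytest.approx(1.2, abs=1e-6)
    assert fit.rms == pytest.approx(0.0, abs=1e-9)
    # e-folding property: at x = tau the curve is C0/e (a ~63% change)
    assert fit.c0 * np.exp(-fit.tau / fit.tau) == pytest.approx(fit.c0 / np.e)


def test_turnover_fit_respects_window_and_minimum_pairs():
    x = np.array([0.1, 0.2, 2.0, 3.0, 4.0, 5.0])
    y = 50 * np.exp(-x)
    with pytest.raises(ValueError, match="at least 5"):
        turnover_fit(y, x, t_max=1.5)  # only 2 pairs inside the window


def test_turnover_fit_from_matrices_uses_similarity():
    x = np.linspace(0.05, 1.4, 28)
    n = 8
    iu = np.triu_indices(n, 1)
    T = np.zeros((n, n))
    T[iu] = x
    T += T.T
    D = np.zeros((n, n))
    D[iu] = 100 - 60 * np.exp(-x / 0.9)
    D += D.T
    fit = turnover_fit_from_matrices(D, T, t_max=1.5)
    assert fit.tau == pytest.approx(0.9, abs=1e-6)
    assert fit.c0 == pytest.approx(60.0, abs=1e-6)


def test_turnover_residuals_mean_zero_for_correct_model():
    rng = np.random.default_rng(9)
    x = rng.uniform(0.05, 1.4, size=200)
    y = 70 * np.exp(-x / 1.1)
    fit = turnover_fit(y, x)
    resid = y - fit.c0 * np.exp(-x / fit.tau)
    assert abs(resid.mean()) < 1e-8


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def test_anosim_perfectly_separated_groups_give_r_one():
    v = np.full((8, 8), 90.0)
    v[:4, :4] = 10.0
    v[4:, 4:] = 10.0
    np.fill_diagonal(v, 0.0)
    res = anosim(v, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=0)
    assert res.r_statistic == pytest.approx(1.0)
    assert res.p_value < 0.05


def test_anosim_null_mean_r_near_zero():
    rng = np.random.default_rng(10)
    rs = []
    for _ in range(200):
        base = rng.uniform(0, 100, size=(8, 8))
        v = (base + base.T) / 2
        np.fill_diagonal(v, 0)
        labels = rng.permutation(["a"] * 4 + ["b"] * 4)
        res = anosim(v, labels, n_perm=99, seed=0)
        rs.append(res.r_statistic)
    assert abs(np.mean(rs)) < 0.05


def test_anosim_deterministic_and_excludes_singletons():
    rng = np.random.default_rng(11)
    base = rng.uniform(0, 100, size=(7, 7))
    v = (base + base.T) / 2
    np.fill_diagonal(v, 0)
    labels = ["a", "a", "a", "b", "b", "b", "c"]
    with pytest.warns(UserWarning, match="singleton"):
        r1 = anosim(v, labels, n_perm=99, seed=3)
    with pytest.warns(UserWarning, match="singleton"):
        r2 = anosim(v, labels, n_perm=99, seed=3)
    assert r1.p_value == r2.p_value


def test_anosim_agrees_with_skbio_reference():
    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.distance import anosim as skbio_anosim

    rng = np.random.default_rng(12)
    base = rng.uniform(1, 99, size=(10, 10))
    v = (base + base.T) / 2
    np.fill_diagonal(v, 0)
    labels = ["a"] * 5 + ["b"] * 5
    mine = anosim(v, labels, n_perm=99, seed=0)
    ref = skbio_anosim(SkbioDM(v), grouping=labels, permutations=0)
    assert mine.r_statistic == pytest.approx(ref["test statistic"], abs=1e-12)
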