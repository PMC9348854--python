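"""UPGMA clustering, bootstrap support, silhouette partitioning, KW screen."""

import numpy as np
import pandas as pd
import pytest

import seascape as ss
from seascape.matrices import DissimilarityMatrix
from seascape.provinces import (
    UNASSIGNED,
    bootstrap_support,
    cut_provinces,
    kruskal_wallis_screen,
    silhouette_scores,
    upgma,
)

from conftest import random_dissimilarity


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma_oracle_cophenetic(D):
    """Textbook O(n^3) UPGMA: returns the cophenetic distance matrix."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        merged = clusters[a] + clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        del clusters[a], clusters[b]
        new_d = {}
        for c in clusters:
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            new_d[c] = (na * dist[key_a] + nb * dist[key_b]) / (na + nb)
        dist = {
            (min(i, j), max(i, j)): v
            for (i, j), v in dist.items()
            if a not in (i, j) and b not in (i, j)
        }
        for c, v in new_d.items():
            dist[(min(c, next_id), max(c, next_id))] = v
        clusters[next_id] = merged
        next_id += 1
    return coph


def test_upgma_two_samples_single_merge():
    D = DissimilarityMatrix(ids=["a", "b"], values=[[0, 6], [6, 0]])
    tree = upgma(D)
    assert tree.linkage.shape == (1, 4)
    assert tree.linkage[0, 2] == pytest.approx(6.0)


def test_upgma_three_samples_average_linkage_height():
    D = DissimilarityMatrix(
        ids=["A", "B", "C"], values=[[0, 2, 8], [2, 0, 8], [8, 8, 0]]
    )
    tree = upgma(D)
    assert tree.linkage[0, 2] == pytest.approx(2.0)
    assert tree.linkage[1, 2] == pytest.approx(8.0)  # average of 8 and 8


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_upgma_cophenetic_matches_textbook_oracle(seed):
    rng = np.random.default_rng(seed)
    D = random_dissimilarity(8, rng)
    tree = upgma(D)
    assert np.allclose(tree.cophenetic(), upgma_oracle_cophenetic(D.values), atol=1e-9)


def test_upgma_cophenetic_is_ultrametric():
    rng = np.random.default_rng(77)
    D = random_dissimilarity(10, rng)
    coph = upgma(D).cophenetic()
    n = coph.shape[0]
    worst = max(
        coph[i, k] - max(coph[i, j], coph[j, k])
        for i in range(n)
        for j in range(n)
        for k in range(n)
    )
    assert worst <= 1e-12


def test_upgma_rejects_nan():
    D = DissimilarityMatrix(ids=["a", "b"], values=[[0, 1], [1, 0]])
    D.values[0, 1] = D.values[1, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        upgma(D)


def test_newick_export_contains_all_leaves_and_supports():
    rng = np.random.default_rng(1)
    D = random_dissimilarity(5, rng)
    tree = upgma(D)
    tree.supports = {s: 0.9 for s in tree.node_leafsets()}
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for leaf in D.ids:
        assert leaf in nwk
    assert "0.900" in nwk


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def block_table(n_per_block=4, n_feat=25, seed=0):
    """Two sample blocks with disjoint feature sets."""
    rng = np.random.default_rng(seed)
    a = np.zeros((2 * n_per_block, 2 * n_feat), dtype=int)
    a[:n_per_block, :n_feat] = rng.integers(0, 2, (n_per_block, n_feat)) | 1
    a[n_per_block:, n_feat:] = rng.integers(0, 2, (n_per_block, n_feat)) | 1
    return pd.DataFrame(a, index=[f"s{i}" for i in range(2 * n_per_block)])


def test_bootstrap_support_full_for_disjoint_blocks():
    table = block_table()
    D = ss.jaccard_dissimilarity(table)
    tree = upgma(D)
    boot = bootstrap_support(tree, table, n_boot=200, seed=0)
    block_a = frozenset(table.index[:4])
    block_b = frozenset(table.index[4:])
    assert boot.supports[block_a] == pytest.approx(1.0)
    assert boot.supports[block_b] == pytest.approx(1.0)


def test_bootstrap_support_is_seed_deterministic():
    table = block_table(seed=3)
    D = ss.jaccard_dissimilarity(table)
    tree = upgma(D)
    b1 = bootstrap_support(tree, table, n_boot=100, seed=5)
    b2 = bootstrap_support(tree, table, n_boot=100, seed=5)
    assert b1.supports == b2.supports


def test_bootstrap_support_low_for_structureless_features():
    rng = np.random.default_rng(8)
    table = pd.DataFrame(
        rng.integers(0, 2, size=(8, 60)), index=[f"s{i}" for i in range(8)]
    )
    table.iloc[:, 0] = 1
    D = ss.jaccard_dissimilarity(table)
    tree = upgma(D)
    boot = bootstrap_support(tree, table, n_boot=200, seed=1)
    sets = tree.node_leafsets()
    shallow = [s for s in sets if len(s) < 8]
    assert np.mean([boot.supports[s] for s in shallow]) < 0.6


def test_bootstrap_support_rejects_mismatched_samples():
    table = block_table()
    D = ss.jaccard_dissimilarity(table)
    tree = upgma(D)
    bad = table.rename(index={"s0": "zz"})
    with pytest.raises(ValueError, match="match"):
        bootstrap_support(tree, bad, n_boot=100)


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def silhouette_oracle(V, labels):
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([V[i, j] for j in own])
        b = min(
            np.mean([V[i, j] for j in range(n) if labels[j] == g])
            for g in set(labels)
            if g != labels[i]
        )
        out[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


def test_silhouette_formula_cases():
    # a == b -> 0 ; a = 0 -> 1 ; a=2, b=4 -> 0.5
    V = np.array(
        [
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ],
        dtype=float,
    )
    D = DissimilarityMatrix(ids=list("abcd"), values=V)
    s = silhouette_scores(D, pd.Series(["x", "x", "y", "y"], index=list("abcd")))
    assert np.allclose(s, 0.5)  # a=2, b=4 for every sample


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_silhouette_matches_brute_force_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    D = random_dissimilarity(10, rng)
    labels = rng.integers(0, 3, size=10)
    s = silhouette_scores(D, pd.Series(labels, index=D.ids))
    assert np.allclose(s.to_numpy(), silhouette_oracle(D.values, labels), atol=1e-12)


def test_silhouette_rejects_mismatched_labels():
    D = random_dissimilarity(4, np.random.default_rng(0))
    with pytest.raises(ValueError, match="match"):
        silhouette_scores(D, pd.Series([0, 1], index=["S0", "S1"]))


# ---------------------------------------------------------------------------
# province cut
# ---------------------------------------------------------------------------

def two_block_matrix(n=8, within=4.0, between=96.0):
    v = np.full((n, n), between)
    h = n // 2
    v[:h, :h] = within
    v[h:, h:] = within
    np.fill_diagonal(v, 0.0)
    return DissimilarityMatrix(ids=[f"s{i}" for i in range(n)], values=v)


def test_cut_recovers_two_perfect_blocks():
    D = two_block_matrix()
    part = cut_provinces(upgma(D), D)
    assert part.n_provinces == 2
    labels = part.labels
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert labels.iloc[0] != labels.iloc[-1]
    assert part.silhouette.mean() > 0.9


def test_far_outlier_is_left_unassigned():
    D = two_block_matrix(n=8)
    v = D.values.copy()
    v = np.pad(v, ((0, 1), (0, 1)), constant_values=99.9)
    v[-1, -1] = 0.0
    D9 = DissimilarityMatrix(ids=[f"s{i}" for i in range(9)], values=v)
    part = cut_provinces(upgma(D9), D9)
    assert part.labels.iloc[-1] == UNASSIGNED
    assert part.n_provinces == 2


def test_k_max_restricts_the_cut_search():
    # three clear blocks but k_max = 2 -> only 2 provinces possible
    v = np.full((9, 9), 90.0)
    for b in range(3):
        v[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = 5.0
    np.fill_diagonal(v, 0.0)
    D = DissimilarityMatrix(ids=[f"s{i}" for i in range(9)], values=v)
    part = cut_provinces(upgma(D), D, k_max=2)
    assert part.n_provinces == 2


def test_cut_never_returns_singleton_province():
    rng = np.random.default_rng(123)
    for _ in range(5):
        D = random_dissimilarity(9, rng)
        part = cut_provinces(upgma(D), D)
        counts = part.labels[part.labels != UNASSIGNED].value_counts()
        assert (counts >= 2).all()


def test_low_support_clusters_are_dissolved():
    D = two_block_matrix()
    tree = upgma(D)
    tree.supports = {s: 0.1 for s in tree.node_leafsets()}
    part = cut_provinces(tree, D, min_support=0.5)
    assert part.n_provinces == 0
    assert (part.labels == UNASSIGNED).all()


# ---------------------------------------------------------------------------
# Kruskal-Wallis screen
# ---------------------------------------------------------------------------

def make_partition(labels, ids):
    s = pd.Series(labels, index=ids)
    return ss.ProvincePartition(
        labels=s, silhouette=pd.Series(0.5, index=ids), support={}, n_provinces=2
    )


def test_kw_constant_parameter_gives_h_zero():
    ids = [f"s{i}" for i in range(8)]
    part = make_partition(["P1"] * 4 + ["P2"] * 4, ids)
    env = pd.DataFrame({"const": np.ones(8)}, index=ids)
    res = kruskal_wallis_screen(env, part, alpha=1e-5)
    assert res[0].h_statistic == 0.0 and res[0].p_value == 1.0


def kw_oracle(groups):
    """Rank-sum H with tie correction, independently coded."""
    from scipy.stats import rankdata

    flat = np.concatenate(groups)
    ranks = rankdata(flat)
    n = len(flat)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


def test_kw_matches_rank_sum_oracle_for_separated_groups():
    ids = [f"s{i}" for i in range(8)]
    part = make_partition(["P1"] * 4 + ["P2"] * 4, ids)
    env = pd.DataFrame({"x": [1, 2, 3, 4, 10, 11, 12, 13.0]}, index=ids)
    res = kruskal_wallis_screen(env, part, alpha=0.05)
    expected = kw_oracle([env["x"][:4].to_numpy(), env["x"][4:].to_numpy()])
    assert res[0].h_statistic == pytest.approx(expected, abs=1e-12)


def test_kw_null_rejection_rate_is_calibrated():
    """Permuted labels reject at about the nominal alpha = 0.05."""
    rng = np.random.default_rng(42)
    ids = [f"s{i}" for i in range(12)]
    rejections = 0
    reps = 2000
    from scipy.stats import kruskal

    for _ in range(reps):
        x = rng.normal(size=12)
        labels = rng.permutation([0] * 6 + [1] * 6)
        _, p = kruskal(x[labels == 0], x[labels == 1])
        rejections += p < 0.05
    rate = rejections / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < 3.5 * se


def test_kw_requires_two_provinces():
    ids = [f"s{i}" for i in range(4)]
    part = make_partition(["P1"] * 4, ids)
    part.n_provinces = 1
    env = pd.DataFrame({"x": [1, 2, 3, 4.0]}, index=ids)
    with pytest.raises(ValueError):
        kruskal_wallis_screen(env, part)
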