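"""Delineation of genomic provinces from a dissimilarity matrix.

Stations are clustered by UPGMA (average linkage) on community
dissimilarities; cluster stability is assessed by bootstrapping the
underlying feature (presence) matrix; the partition into provinces is
chosen among horizontal cuts of the dendrogram as the one maximizing the
mean silhouette, with unsupported clusters and singletons dissolved to
the unassigned label "-". Single samples are never provinces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.stats import chi2, kruskal

from .beta import bray_curtis_dissimilarity, jaccard_dissimilarity
from .matrices import DissimilarityMatrix

__all__ = [
    "Dendrogram",
    "ProvincePartition",
    "KWResult",
    "upgma",
    "bootstrap_support",
    "silhouette_scores",
    "cut_provinces",
    "kruskal_wallis_screen",
]

UNASSIGNED = "-"


@dataclass
class Dendrogram:
    """A UPGMA tree over samples, with optional bootstrap proportions.

    ``linkage`` is a scipy linkage matrix; ``supports`` maps each internal
    node (as a frozenset of leaf ids) to its bootstrap proportion.
    """

    ids: list[str]
    linkage: np.ndarray
    supports: dict[frozenset, float] | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def node_leafsets(self) -> list[frozenset]:
        """Leaf-id sets of the n-1 internal nodes, in merge order."""
        sets: list[frozenset] = [frozenset([i]) for i in self.ids]
        out = []
        for left, right, _, _ in self.linkage:
            s = sets[int(left)] | sets[int(right)]
            sets.append(s)
            out.append(s)
        return out

    def cophenetic(self) -> np.ndarray:
        """Square cophenetic distance matrix in input units."""
        from scipy.spatial.distance import squareform

        return squareform(cophenet(self.linkage))

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (0..k-1) for the horizontal cut giving k clusters."""
        return cut_tree(self.linkage, n_clusters=k).ravel()

    def to_newick(self) -> str:
        """Newick string with bootstrap proportions as internal node labels."""
        heights = self.linkage[:, 2]
        supports = self.supports or {}
        sets = self.node_leafsets()

        def node_height(idx: int) -> float:
            return 0.0 if idx < self.n else heights[idx - self.n]

        def render(idx: int, parent_h: float) -> str:
            length = parent_h - node_height(idx)
            if idx < self.n:
                return f"{self.ids[idx]}:{length:g}"
            row = self.linkage[idx - self.n]
            children = ",".join(
                render(int(c), node_height(idx)) for c in row[:2]
            )
            bp = supports.get(sets[idx - self.n])
            label = f"{bp:.3f}" if bp is not None else ""
            return f"({children}){label}:{length:g}"

        root = 2 * self.n - 2
        row = self.linkage[-1]
        children = ",".join(render(int(c), node_height(root)) for c in row[:2])
        bp = supports.get(sets[-1])
        label = f"{bp:.3f}" if bp is not None else ""
        return f"({children}){label};"


@dataclass
class ProvincePartition:
    """Province labels with per-sample silhouettes and per-province support."""

    labels: pd.Series  # sample -> province id or "-"
    silhouette: pd.Series  # sample -> s in [-1, 1]
    support: dict[str, float]  # province -> bootstrap proportion (may be nan)
    n_provinces: int

    def __post_init__(self) -> None:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        if (counts < 2).any():
            raise ValueError("a province must have at least 2 members")


@dataclass
class KWResult:
    parameter: str
    h_statistic: float
    df: int
    p_value: float
    significant: bool


def upgma(D: DissimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering with arithmetic-average (UPGMA) linkage.

    Merge heights are inter-cluster average dissimilarities, so the
    cophenetic distances are ultrametric.
    """
    if D.n < 2:
        raise ValueError("need at least 2 samples")
    cond = D.condensed()
    if np.isnan(cond).any():
        raise ValueError("dissimilarity matrix contains NaN entries")
    Z = linkage(cond, method="average")
    return Dendrogram(ids=list(D.ids), linkage=Z)


_METRICS = {"jaccard": jaccard_dissimilarity, "bray_curtis": bray_curtis_dissimilarity}


def bootstrap_support(
    tree: Dendrogram,
    feature_table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    metric: str = "jaccard",
    max_features: int | None = 100_000,
) -> Dendrogram:
    """Ordinary bootstrap proportions for the internal nodes of ``tree``.

    Feature columns of the samples x features table underlying the
    dissimilarity matrix are resampled with replacement; the matrix and
    UPGMA tree are recomputed per replicate; each original internal node
    is scored by the fraction of replicate trees containing an identical
    leaf set. Tables wider than ``max_features`` are reduced to a seeded
    random subset of columns before resampling.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ids = [str(i) for i in feature_table.index]
    if set(ids) != set(tree.ids):
        raise ValueError("feature table samples do not match the tree's ids")
    table = feature_table.loc[tree.ids]
    values = table.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n_feat = values.shape[1]
    if max_features is not None and n_feat > max_features:
        keep = rng.choice(n_feat, size=max_features, replace=False)
        values = values[:, keep]
        n_feat = max_features

    metric_fn = _METRICS[metric]
    targets = tree.node_leafsets()
    hits = dict.fromkeys(targets, 0)
    dummy_cols = [f"f{j}" for j in range(n_feat)]
    for _ in range(n_boot):
        cols = rng.integers(0, n_feat, size=n_feat)
        boot = pd.DataFrame(values[:, cols], index=tree.ids, columns=dummy_cols)
        try:
            Db = metric_fn(boot)
        except ValueError:  # a replicate emptied some sample
            continue
        boot_sets = set(upgma(Db).node_leafsets())
        for t in targets:
            if t in boot_sets:
                hits[t] += 1
    supports = {t: hits[t] / n_boot for t in targets}
    return Dendrogram(ids=tree.ids, linkage=tree.linkage, supports=supports)


def silhouette_scores(D: DissimilarityMatrix, labels) -> pd.Series:
    """Per-sample silhouette ``s = (b - a) / max(a, b)`` from a distance matrix.

    ``a`` is the mean distance to the other members of the sample's own
    cluster and ``b`` the smallest mean distance to another cluster.
    Samples in singleton clusters get s = 0 by convention.
    """
    labels = pd.Series(labels, index=D.ids) if not isinstance(labels, pd.Series) else labels
    if set(labels.index) != set(D.ids):
        raise ValueError("label index does not match the matrix ids")
    lab = labels.loc[D.ids].to_numpy()
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    V = D.values
    n = D.n
    s = np.zeros(n)
    for i in range(n):
        own = lab == lab[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = V[i, own].sum() / (n_own - 1)
        b = min(V[i, lab == g].mean() for g in uniq if g != lab[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return pd.Series(s, index=D.ids, name="silhouette")


def cut_provinces(
    tree: Dendrogram,
    D: DissimilarityMatrix,
    min_support: float = 0.5,
    k_max: int | None = None,
) -> ProvincePartition:
    """Partition a UPGMA tree into provinces by maximal mean silhouette.

    Every horizontal cut giving 2..k_max clusters is evaluated; the cut
    maximizing the mean silhouette over all samples (samples in singleton
    clusters contributing their conventional s = 0) is selected.
    Clusters of size 1, and clusters whose bootstrap
    proportion falls below ``min_support`` (when supports are available),
    are dissolved to the unassigned label "-".
    """
    n = tree.n
    if k_max is None:
        k_max = min(n - 1, 15)
    if not (2 <= k_max <= n - 1):
        raise ValueError("k_max must lie in [2, n-1]")

    best_k, best_mean, best_labels, best_sil = None, -np.inf, None, None
    for k in range(2, k_max + 1):
        lab = tree.cut(k)
        sizes = np.bincount(lab)
        eligible = sizes[lab] >= 2
        if not eligible.any():
            continue
        sil = silhouette_scores(D, pd.Series(lab, index=tree.ids))
        # singletons contribute their conventional s = 0 to the mean, so a
        # cut cannot win by shedding most samples as singletons
        mean_s = (sil.to_numpy() * eligible).mean()
        if mean_s > best_mean + 1e-12:
            best_k, best_mean, best_labels, best_sil = k, mean_s, lab, sil

    ids = tree.ids
    if best_labels is None:
        warnings.warn("all candidate cuts yield only singletons; no provinces")
        empty = pd.Series([UNASSIGNED] * n, index=ids)
        return ProvincePartition(
            labels=empty,
            silhouette=pd.Series(np.zeros(n), index=ids),
            support={},
            n_provinces=0,
        )

    supports = tree.supports or {}
    leaf_sets = {}
    for g in np.unique(best_labels):
        members = frozenset(np.array(ids)[best_labels == g])
        leaf_sets[g] = members

    final = pd.Series([UNASSIGNED] * n, index=ids)
    support_out: dict[str, float] = {}
    next_id = 1
    for g in np.unique(best_labels):
        members = leaf_sets[g]
        if len(members) < 2:
            continue
        bp = supports.get(members, np.nan)
        if supports and not np.isnan(bp) and bp < min_support:
            continue
        name = f"P{next_id}"
        next_id += 1
        final[list(members)] = name
        support_out[name] = float(bp)
    if (final == UNASSIGNED).all():
        warnings.warn("no cluster met the support/size rules; no provinces")
    return ProvincePartition(
        labels=final,
        silhouette=best_sil,
        support=support_out,
        n_provinces=len(support_out),
    )


def kruskal_wallis_screen(
    env_table: pd.DataFrame,
    partition: ProvincePartition,
    alpha: float = 1e-5,
) -> list[KWResult]:
    """Kruskal-Wallis H test of each environmental parameter across provinces.

    Restricted to assigned samples; the rank-based H statistic with tie
    correction is referred to a chi-square approximation. A parameter
    constant across all samples yields H = 0, p = 1.
    """
    assigned = partition.labels[partition.labels != UNASSIGNED]
    groups = assigned.groupby(assigned).groups
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 provinces of size >= 2")
    results = []
    for param in env_table.columns:
        samples = [
            env_table.loc[list(members), param].dropna().to_numpy()
            for members in groups.values()
        ]
        df = len(samples) - 1
        flat = np.concatenate(samples)
        if np.allclose(flat, flat[0]):
            h, p = 0.0, 1.0
        else:
            h, p = kruskal(*samples)
        results.append(
            KWResult(
                parameter=str(param),
                h_statistic=float(h),
                df=df,
                p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    return results
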