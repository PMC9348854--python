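"""Correlation machinery and environmental statistics.

Distance-matrix correlations (Spearman, Mantel permutation test,
first-order partial Spearman), cumulative correlation curves against a
travel-time ceiling, the exponential community-turnover fit
``y = C0 exp(-x / tau)`` whose e-folding time ``tau`` is the time over
which fitted community similarity decays by a factor of e (a ~63%
change), ANOSIM, z-scored environmental Euclidean distances, light
attenuation (PAR at depth from surface PAR and chlorophyll), and
seasonality indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import rankdata

from .matrices import DissimilarityMatrix

__all__ = [
    "EnvDistanceMatrix",
    "CorrelationCurve",
    "ExponentialFit",
    "AnosimResult",
    "env_distance",
    "par_at_depth",
    "seasonality_index",
    "spearman",
    "mantel",
    "partial_spearman",
    "cumulative_correlation",
    "turnover_fit",
    "anosim",
]


# ---------------------------------------------------------------------------
# environmental distances and indices
# ---------------------------------------------------------------------------

@dataclass
class EnvDistanceMatrix:
    """Euclidean distances between stations in z-scored parameter space."""

    ids: list[str]
    values: np.ndarray
    params: list[str]


def env_distance(
    env: pd.DataFrame, params: list[str], zero_floor: float = 1e-6
) -> EnvDistanceMatrix:
    """Euclidean distance over a z-scored parameter subset.

    Each parameter is scaled to mean 0, variance 1 over the included
    stations so all contribute equally. Ratio-style parameters should be
    built beforehand with denominators of zero replaced by
    ``zero_floor`` (see :func:`nutrient_ratio`).
    """
    if not params:
        raise ValueError("params must be non-empty")
    X = env[list(params)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [p for p, s in zip(params, sd) if s == 0]
        raise ValueError(f"parameters with zero variance: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return EnvDistanceMatrix(
        ids=[str(i) for i in env.index], values=values, params=list(params)
    )


def nutrient_ratio(num: pd.Series, den: pd.Series, zero_floor: float = 1e-6) -> pd.Series:
    """Ratio of two parameters with zero denominators floored."""
    d = den.where(den != 0, zero_floor)
    return num / d


def par_at_depth(par0: float, chl: float, z_eval: float) -> float:
    """Photosynthetically active radiation at depth ``z_eval`` metres.

    Uses the chlorophyll-based attenuation relation: with
    ``x = log10(Chl)``, the reference depth is
    ``Z = 10 ** (1.524 - 0.426 x - 0.0145 x^2 + 0.0186 x^3)`` and the
    attenuation coefficient ``k = -ln(0.01) / Z``, so PAR falls to 1% of
    its surface value at Z. Returns ``par0 * exp(-k * z_eval)``.
    """
    if chl <= 0:
        raise ValueError("chlorophyll must be positive")
    if par0 < 0 or z_eval < 0:
        raise ValueError("par0 and z_eval must be non-negative")
    x = np.log10(chl)
    Z = 10.0 ** (1.524 - 0.426 * x - 0.0145 * x**2 + 0.0186 * x**3)
    k = -np.log(0.01) / Z
    return float(par0 * np.exp(-k * z_eval))


def seasonality_index(monthly_table: pd.DataFrame) -> pd.Series:
    """Annual range per station divided by the largest range over stations.

    ``monthly_table`` is stations x months. The station with the largest
    annual variation gets SI = 1; a constant series gets SI = 0.
    """
    ranges = monthly_table.max(axis=1) - monthly_table.min(axis=1)
    top = ranges.max()
    if top == 0:
        raise ValueError("all stations are constant; seasonality undefined")
    return (ranges / top).rename("SI")


# ---------------------------------------------------------------------------
# matrix correlations
# ---------------------------------------------------------------------------

def _as_values(M) -> np.ndarray:
    if isinstance(M, DissimilarityMatrix):
        return M.values
    if isinstance(M, EnvDistanceMatrix):
        return M.values
    return np.asarray(M, dtype=float)


def _pair_values(M, mask: np.ndarray | None):
    """Off-diagonal upper-triangle values, optionally restricted by mask."""
    V = _as_values(M)
    iu = np.triu_indices(V.shape[0], k=1)
    vals = V[iu]
    sel = np.ones(len(vals), dtype=bool) if mask is None else np.asarray(mask)[iu]
    return vals, sel


def spearman(D1, D2, pair_mask: np.ndarray | None = None) -> float:
    """Spearman correlation over selected unordered station pairs.

    Values are average-ranked and Pearson-correlated. Pairs where either
    matrix is NaN are dropped; with fewer than 3 usable pairs the result
    is NaN.
    """
    v1, sel = _pair_values(D1, pair_mask)
    v2, _ = _pair_values(D2, pair_mask)
    sel = sel & np.isfinite(v1) & np.isfinite(v2)
    x, y = v1[sel], v2[sel]
    if len(x) < 3:
        return float("nan")
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else float("nan")


def mantel(
    D1,
    D2,
    pair_mask: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel permutation test of the masked Spearman correlation.

    Station identities of D1 are permuted jointly over rows and columns
    while the pair mask stays fixed to D2's pairs;
    ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    V1 = _as_values(D1)
    rho = spearman(V1, D2, pair_mask)
    if np.isnan(rho):
        return rho, float("nan")
    rng = np.random.default_rng(seed)
    n = V1.shape[0]
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        rp = spearman(V1[np.ix_(p, p)], D2, pair_mask)
        if np.isfinite(rp) and abs(rp) >= abs(rho) - 1e-15:
            hits += 1
    return rho, (1 + hits) / (1 + n_perm)


def partial_spearman(D1, D2, D3, pair_mask: np.ndarray | None = None) -> float:
    """First-order partial Spearman correlation of D1 and D2 given D3.

    ``(r12 - r13 r23) / sqrt((1 - r13^2)(1 - r23^2))`` on masked
    Spearman correlations.
    """
    r12 = spearman(D1, D2, pair_mask)
    r13 = spearman(D1, D3, pair_mask)
    r23 = spearman(D2, D3, pair_mask)
    if abs(r13) >= 1 - 1e-12 or abs(r23) >= 1 - 1e-12:
        raise ValueError(
            "control matrix is perfectly correlated with an input; "
            "partial correlation undefined"
        )
    return float((r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2)))


@dataclass
class CorrelationCurve:
    """Spearman rho as a function of a travel-time ceiling."""

    thresholds: np.ndarray  # years
    rho: np.ndarray
    n_pairs: np.ndarray
    p: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.thresholds,
                "rho": self.rho,
                "n_pairs": self.n_pairs,
                "p": self.p,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )

    def argmax_threshold(self) -> float:
        """Ceiling with the largest correlation (NaN entries ignored)."""
        if np.all(np.isnan(self.rho)):
            return float("nan")
        return float(self.thresholds[np.nanargmax(self.rho)])


def cumulative_correlation(
    D,
    T: np.ndarray,
    thresholds: np.ndarray,
    min_pairs: int = 10,
    n_perm: int = 0,
    n_boot: int = 0,
    seed: int = 0,
) -> CorrelationCurve:
    """Correlation between D and T over pairs with ``T < t``, per ceiling t.

    ``T`` is a symmetrized travel-time matrix (NaN = unconnected pair).
    Optionally adds a Mantel p-value (``n_perm`` > 0) and a 95% CI from a
    station-level bootstrap (``n_boot`` > 0; stations are resampled with
    replacement and self-pairs dropped, respecting pairwise dependence).
    Ceilings with fewer than ``min_pairs`` usable pairs are NaN.
    """
    V = _as_values(D)
    T = np.asarray(T, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    n = V.shape[0]
    rng = np.random.default_rng(seed)
    rho = np.full(len(thresholds), np.nan)
    npairs = np.zeros(len(thresholds), dtype=int)
    pvals = np.full(len(thresholds), np.nan)
    ci_lo = np.full(len(thresholds), np.nan)
    ci_hi = np.full(len(thresholds), np.nan)
    for i, t in enumerate(thresholds):
        mask = np.isfinite(T) & (T < t)
        iu = np.triu_indices(n, k=1)
        npairs[i] = int(mask[iu].sum())
        if npairs[i] < min_pairs:
            continue
        rho[i] = spearman(V, T, mask)
        if n_perm > 0:
            _, pvals[i] = mantel(V, T, mask, n_perm=n_perm, seed=seed + i)
        if n_boot > 0:
            boots = []
            for _ in range(n_boot):
                s = rng.integers(0, n, size=n)
                distinct = s[:, None] != s[None, :]
                bmask = mask[np.ix_(s, s)] & distinct
                rb = spearman(V[np.ix_(s, s)], T[np.ix_(s, s)], bmask)
                if np.isfinite(rb):
                    boots.append(rb)
            if len(boots) >= 20:
                ci_lo[i], ci_hi[i] = np.percentile(boots, [2.5, 97.5])
    return CorrelationCurve(
        thresholds=thresholds, rho=rho, n_pairs=npairs, p=pvals, ci_lo=ci_lo, ci_hi=ci_hi
    )


# ---------------------------------------------------------------------------
# turnover fit
# ---------------------------------------------------------------------------

@dataclass
class ExponentialFit:
    """Exponential decay fit y = C0 exp(-x / tau)."""

    c0: float
    tau: float  # e-folding time, years
    rms: float
    n: int
    t_max: float


def turnover_fit(
    similarity: np.ndarray,
    tmin: np.ndarray,
    t_max: float = 1.5,
) -> ExponentialFit:
    """Fit ``y = C0 exp(-x / tau)`` to similarity-vs-travel-time pairs.

    ``similarity`` is community similarity (100 - dissimilarity) per
    station pair and ``tmin`` the symmetrized minimum travel time in
    years; only pairs with ``tmin < t_max`` enter the fit. ``tau`` is the
    e-folding time: at x = tau the fitted similarity has decayed by a
    factor of e (~63%) from C0.
    """
    y = np.asarray(similarity, dtype=float)
    x = np.asarray(tmin, dtype=float)
    sel = np.isfinite(x) & np.isfinite(y) & (x < t_max)
    x, y = x[sel], y[sel]
    if len(x) < 5:
        raise ValueError(f"need at least 5 pairs with T < {t_max}; got {len(x)}")
    p0 = (max(y.max(), 1e-6), max(float(np.median(x)), 1e-3))
    try:
        popt, _ = curve_fit(
            lambda t, c0, tau: c0 * np.exp(-t / tau), x, y, p0=p0, maxfev=10000
        )
    except RuntimeError as e:
        raise ValueError(f"turnover fit did not converge: {e}") from e
    c0, tau = float(popt[0]), float(popt[1])
    if tau <= 0:
        raise ValueError(f"turnover fit produced non-positive tau = {tau:g}")
    resid = y - c0 * np.exp(-x / tau)
    return ExponentialFit(
        c0=c0, tau=tau, rms=float(np.sqrt((resid**2).mean())), n=len(x), t_max=t_max
    )


def turnover_fit_from_matrices(D, T: np.ndarray, t_max: float = 1.5) -> ExponentialFit:
    """Convenience wrapper: turnover fit from a dissimilarity matrix (percent
    scale) and a symmetrized travel-time matrix."""
    V = _as_values(D)
    iu = np.triu_indices(V.shape[0], k=1)
    return turnover_fit(100.0 - V[iu], np.asarray(T, dtype=float)[iu], t_max=t_max)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int


def anosim(D, group_labels, n_perm: int = 1000, seed: int = 0) -> AnosimResult:
    """Analysis of similarities: between- vs within-group distance ranks.

    ``R = (mean rank between - mean rank within) / (M / 2)`` with
    ``M = n(n-1)/2``; the p-value is the fraction of group relabelings
    with R at least as large. Groups of size 1 are excluded with a
    warning.
    """
    V = _as_values(D)
    labels = np.asarray(group_labels)
    counts = pd.Series(labels).value_counts()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(f"excluding singleton groups: {list(singletons)}")
        keep = ~np.isin(labels, singletons)
        V = V[np.ix_(keep, keep)]
        labels = labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 groups of size >= 2")

    n = V.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(V[iu])
    M = n * (n - 1) / 2

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs - 1e-15:
            hits += 1
    return AnosimResult(
        r_statistic=float(r_obs), p_value=(1 + hits) / (1 + n_perm), n_permutations=n_perm
    )
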