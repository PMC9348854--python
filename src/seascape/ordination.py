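"""Ordination of samples and RGB color encoding of their positions.

Community dissimilarities are embedded by classical scaling (PCoA) with
the Cailliez additive correction when the matrix is not Euclidean;
environmental tables are Box-Cox transformed, z-scaled, reduced by PCA
and whitened. The first three axes (x, y, z) are mapped to 8-bit color
channels as ``round(128 * (1 + lambda_c * score / max|score|))``, clamped
to [0, 255], where ``lambda_c`` is 1 for the dominant axis and the
ratio of the axis eigenvalue to the dominant one otherwise (or 1 for all
axes in the environmental variant), so that similar colors mean similar
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import boxcox_llf

from .matrices import DissimilarityMatrix

__all__ = ["OrdinationResult", "pcoa", "rgb_from_ordination", "env_ordination"]


@dataclass
class OrdinationResult:
    """Sample scores on the first three ordination axes.

    ``eigenvalues`` holds all axis eigenvalues sorted non-increasing;
    ``lambda_ratios`` is (1, eig2/eig1, eig3/eig1) clipped to [0, 1].
    """

    ids: list[str]
    scores: np.ndarray  # (n, 3)
    eigenvalues: np.ndarray
    additive_constant: float = 0.0

    @property
    def lambda_ratios(self) -> np.ndarray:
        e = self.eigenvalues
        lead = e[0] if len(e) and e[0] > 0 else 1.0
        ratios = np.array([1.0, *(np.clip(e[1:3] / lead, 0.0, 1.0))])
        if len(ratios) < 3:
            ratios = np.pad(ratios, (0, 3 - len(ratios)))
        return ratios


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Make the sample of maximum |score| positive on each axis."""
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if np.abs(col).max() > 0 and col[np.abs(col).argmax()] < 0:
            scores[:, j] = -col
    return scores


def _double_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B1 = -0.5 * J @ (D**2) @ J
    B2 = -0.5 * J @ D @ J
    M = np.block([[np.zeros((n, n)), 2 * B1], [-np.eye(n), -4 * B2]])
    eig = np.linalg.eigvals(M)
    return float(np.max(eig.real))


def pcoa(D: DissimilarityMatrix, eig_tol: float = 1e-8) -> OrdinationResult:
    """Classical scaling of a dissimilarity matrix, top 3 axes.

    Double-centers -0.5 D^2; when any eigenvalue is negative beyond
    tolerance the Cailliez additive constant is applied to the
    off-diagonal dissimilarities first. Axis signs are fixed so the
    sample of maximum absolute score is positive.
    """
    if D.n < 4:
        raise ValueError("PCoA with 3 axes needs at least 4 samples")
    V = D.values.copy()
    add_c = 0.0
    w = np.linalg.eigvalsh(_double_center(V))
    if w.min() < -eig_tol * max(w.max(), 1.0):
        add_c = max(_cailliez_constant(V), 0.0)
        V = V + add_c
        np.fill_diagonal(V, 0.0)
    w, U = np.linalg.eigh(_double_center(V))
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    pos = np.clip(w[:3], 0.0, None)
    scores = _fix_signs(U[:, :3] * np.sqrt(pos))
    return OrdinationResult(
        ids=list(D.ids), scores=scores, eigenvalues=w, additive_constant=add_c
    )


def rgb_from_ordination(
    ord: OrdinationResult, use_eigenvalue_ratios: bool = True
) -> pd.DataFrame:
    """Map 3-axis scores to (r, g, b) channels in [0, 255].

    channel = round(128 * (1 + lambda_c * score / max|score|)), clamped.
    An axis with all-zero scores maps to 128 for every sample. With
    ``use_eigenvalue_ratios`` (the PCoA variant) lambda is the axis
    eigenvalue ratio; otherwise (environmental variant) lambda = 1.
    """
    lam = ord.lambda_ratios if use_eigenvalue_ratios else np.ones(3)
    channels = np.empty((len(ord.ids), 3), dtype=int)
    for j in range(3):
        col = ord.scores[:, j]
        m = np.abs(col).max()
        if m == 0:
            channels[:, j] = 128
        else:
            raw = np.rint(128.0 * (1.0 + lam[j] * col / m))
            channels[:, j] = np.clip(raw, 0, 255).astype(int)
    df = pd.DataFrame(channels, index=ord.ids, columns=["r", "g", "b"])
    df["hex"] = [f"#{r:02x}{g:02x}{b:02x}" for r, g, b in channels]
    return df


def _boxcox_lambda(x: np.ndarray, bounds: tuple[float, float] = (-2.0, 2.0)) -> float:
    res = minimize_scalar(
        lambda lam: -boxcox_llf(lam, x), bounds=bounds, method="bounded"
    )
    return float(res.x)


def env_ordination(env_table: pd.DataFrame) -> OrdinationResult:
    """Box-Cox + PCA ordination of an environmental table (samples x vars).

    Each variable is shifted to be strictly positive if needed, power
    transformed with a maximum-likelihood Box-Cox exponent searched on
    [-2, 2], and z-scaled; PCA retains the top three components, whose
    scores are rescaled to unit variance and whitened so their sample
    covariance is the identity. Constant variables are dropped with a
    warning.
    """
    if len(env_table) < 4:
        raise ValueError("need at least 4 samples")
    cols = []
    for name in env_table.columns:
        x = env_table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"dropping constant environmental variable {name!r}")
            continue
        if x.min() <= 0:
            x = x - x.min() + 1e-6
        lam = _boxcox_lambda(x)
        x = (x**lam - 1.0) / lam if abs(lam) > 1e-12 else np.log(x)
        cols.append((x - x.mean()) / x.std(ddof=0))
    if len(cols) < 3:
        raise ValueError("need at least 3 non-constant environmental variables")
    X = np.column_stack(cols)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    eigenvalues = s**2 / n
    scores = (U * s)[:, :3]
    # unit variance per component, then Mahalanobis whitening
    scores = scores / scores.std(axis=0, ddof=0)
    cov = np.cov(scores, rowvar=False, ddof=0)
    w, V = np.linalg.eigh(cov)
    scores = scores @ (V / np.sqrt(w)) @ V.T
    scores = _fix_signs(scores)
    return OrdinationResult(
        ids=[str(i) for i in env_table.index],
        scores=scores,
        eigenvalues=eigenvalues,
    )
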