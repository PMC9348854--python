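"""Square station-by-station matrices used throughout the pipeline.

The central currency of the analysis is the :class:`DissimilarityMatrix`,
a symmetric matrix of pairwise community dissimilarities on a 0-100
percent scale (0 = identical communities, 100 = completely dissimilar).
Travel-time and geographic-distance matrices share the same TSV layout
(sample ids as header row and first column) but carry their own units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DissimilarityMatrix", "read_square_tsv", "write_square_tsv"]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities on the percent (0-100) scale.

    Parameters
    ----------
    ids : list of str
        Sample identifiers, one per row/column.
    values : ndarray of shape (n, n)
        Symmetric matrix with zero diagonal, entries in [0, 100].
    metric : str
        Tag naming the metric ("kmer", "jaccard", "bray_curtis", ...).
    """

    ids: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if np.nanmin(self.values) < -1e-8 or np.nanmax(self.values) > 100 + 1e-8:
            raise ValueError("dissimilarity values must lie in [0, 100]")
        # enforce exact symmetry / zero diagonal after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, ids: list[str]) -> "DissimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DissimilarityMatrix(
            ids=list(ids), values=self.values[np.ix_(idx, idx)], metric=self.metric
        )

    def to_tsv(self, path) -> None:
        write_square_tsv(path, self.ids, self.values)

    @classmethod
    def from_tsv(cls, path, metric: str = "unknown") -> "DissimilarityMatrix":
        ids, values = read_square_tsv(path)
        return cls(ids=ids, values=values, metric=metric)


def write_square_tsv(path, ids, values) -> None:
    """Write a square matrix as TSV with ids as header row and column."""
    pd.DataFrame(np.asarray(values), index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_square_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError(f"{path}: row and column ids differ; not a square matrix")
    return ids, df.to_numpy(dtype=float)
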