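"""Community dissimilarity metrics.

Three routes to a pairwise :class:`~seascape.matrices.DissimilarityMatrix`:

* alignment-free metagenomic beta-diversity from sets of distinct
  canonical k-mers, ``100 * (b + c) / (2a + b + c)`` where ``a`` counts
  k-mers shared between two samples and ``b``, ``c`` the k-mers specific
  to each;
* presence/absence Jaccard, ``100 * (b + c) / (a + b + c)``, for OTU
  tables;
* Bray-Curtis, ``100 * sum|x - y| / sum(x + y)``, for abundance tables.

K-mers are canonical (the lexicographic minimum of a k-mer and its
reverse complement) because shotgun reads are unstranded; ``k`` must be
odd so a k-mer can never equal its own reverse complement. Profiles are
exact hashed sets encoded as 2-bit-packed ``uint64`` codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import DissimilarityMatrix
from .synth import ReadSet

__all__ = [
    "KmerProfile",
    "filter_low_complexity",
    "subsample_prefix",
    "build_kmer_profile",
    "kmer_dissimilarity",
    "jaccard_dissimilarity",
    "bray_curtis_dissimilarity",
    "shannon_entropy",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i


def _encode(reads: list[str]) -> np.ndarray:
    """Pack same-length reads into a (n, L) uint8 code array (255 = non-ACGT)."""
    arr = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def shannon_entropy(read: str) -> float:
    """Shannon entropy (bits) of the mononucleotide composition of a read.

    Non-ACGT symbols are excluded from the frequencies. A read with no
    ACGT symbols has entropy 0.
    """
    codes = _CODE[np.frombuffer(read.encode("ascii"), dtype=np.uint8)]
    counts = np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def filter_low_complexity(reads: ReadSet, entropy_threshold: float = 1.5) -> ReadSet:
    """Drop whole reads whose base-composition entropy is below threshold.

    Retains exactly the reads with Shannon entropy (bits, over ACGT
    frequencies) >= ``entropy_threshold``, preserving input order.
    """
    if not (0.0 <= entropy_threshold <= 2.0):
        raise ValueError("entropy_threshold must lie in [0, 2]")
    kept = [r for r in reads.reads if shannon_entropy(r) >= entropy_threshold]
    return ReadSet(
        sample_id=reads.sample_id, reads=kept, read_length=reads.read_length
    )


def subsample_prefix(reads: ReadSet, n_reads: int) -> ReadSet:
    """Keep the first ``min(n_reads, available)`` reads in original order."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    return ReadSet(
        sample_id=reads.sample_id,
        reads=reads.reads[:n_reads],
        read_length=reads.read_length,
    )


@dataclass
class KmerProfile:
    """The set of distinct canonical k-mers of one sample.

    ``kmers`` is a sorted array of 2-bit-packed uint64 codes
    (A=0, C=1, G=2, T=3, most significant base first).
    """

    sample_id: str
    k: int
    kmers: np.ndarray
    n_reads_used: int

    @property
    def size(self) -> int:
        return len(self.kmers)

    def as_strings(self) -> set[str]:
        """Decode the profile to literal k-mer strings (small profiles only)."""
        bases = "ACGT"
        out = set()
        for code in self.kmers:
            code = int(code)
            s = []
            for _ in range(self.k):
                s.append(bases[code & 3])
                code >>= 2
            out.add("".join(reversed(s)))
        return out


def _canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes from a (n_reads, L) uint8 array; skips
    windows containing non-ACGT symbols."""
    n, L = codes.shape
    if L < k:
        return np.empty(0, dtype=np.uint64)
    W = L - k + 1
    valid = codes < 4
    ok = np.ones((n, W), dtype=bool)
    fwd = np.zeros((n, W), dtype=np.uint64)
    rev = np.zeros((n, W), dtype=np.uint64)
    safe = np.where(valid, codes, 0).astype(np.uint64)
    comp = np.where(valid, 3 - codes, 0).astype(np.uint64)
    for j in range(k):
        ok &= valid[:, j : j + W]
        fwd = (fwd << np.uint64(2)) | safe[:, j : j + W]
        # reverse complement: complemented bases in reverse window order
        rev |= comp[:, j : j + W] << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)[ok]
    return np.unique(canon)


def build_kmer_profile(
    reads: ReadSet, k: int = 15, sketch_size: int | None = None
) -> KmerProfile:
    """Collect the set of distinct canonical k-mers over all reads.

    ``k`` must be odd: an even k admits palindromic k-mers equal to their
    own reverse complement, which would break canonicalization ties.
    Windows containing any non-ACGT symbol are skipped; reads shorter
    than k contribute nothing.

    ``sketch_size`` switches to an approximate fixed-size bottom sketch:
    only the ``sketch_size`` smallest hashed k-mer codes are kept.
    Overlap counts between bottom sketches estimate the exact ones, at a
    memory cost independent of input size; dissimilarities computed from
    sketches are approximate.
    """
    if not (3 <= k <= 31):
        raise ValueError("k must lie in [3, 31]")
    if k % 2 == 0:
        raise ValueError(
            "k must be odd: even k allows a k-mer to equal its own reverse "
            "complement, making the canonical form ambiguous"
        )
    by_len: dict[int, list[str]] = {}
    for r in reads.reads:
        by_len.setdefault(len(r), []).append(r)
    chunks = []
    for length, group in by_len.items():
        if length < k:
            continue
        arr = _encode(group).reshape(len(group), length)
        chunks.append(_canonical_codes(arr, k))
    kmers = (
        np.unique(np.concatenate(chunks)) if chunks else np.empty(0, dtype=np.uint64)
    )
    if sketch_size is not None and len(kmers) > sketch_size:
        # bottom sketch under a splitmix-style integer hash
        hashed = _mix64(kmers)
        kmers = np.sort(kmers[np.argsort(hashed)[:sketch_size]])
    return KmerProfile(
        sample_id=reads.sample_id, k=k, kmers=kmers, n_reads_used=len(reads.reads)
    )


def _mix64(x: np.ndarray) -> np.ndarray:
    """Avalanching 64-bit integer hash (splitmix64 finalizer)."""
    z = x.astype(np.uint64) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def kmer_dissimilarity(profiles: list[KmerProfile]) -> DissimilarityMatrix:
    """Pairwise distinct-k-mer dissimilarity, ``100 (b+c) / (2a+b+c)``.

    Two empty profiles are 0 (identical) by convention.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"profiles have mixed k values: {sorted(ks)}")
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = np.intersect1d(
                profiles[i].kmers, profiles[j].kmers, assume_unique=True
            ).size
            b = profiles[i].size - a
            c = profiles[j].size - a
            denom = 2 * a + b + c
            values[i, j] = values[j, i] = 100.0 * (b + c) / denom if denom else 0.0
    return DissimilarityMatrix(
        ids=[p.sample_id for p in profiles], values=values, metric="kmer"
    )


def kmer_feature_table(
    profiles: list[KmerProfile],
    max_features: int | None = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Samples x k-mers presence matrix underlying the k-mer dissimilarity.

    The union of all profiles can be very large; when it exceeds
    ``max_features`` a seeded random subset of k-mer columns is kept
    (sufficient for bootstrap support estimation).
    """
    union = np.unique(np.concatenate([p.kmers for p in profiles]))
    if max_features is not None and len(union) > max_features:
        rng = np.random.default_rng(seed)
        union = np.sort(rng.choice(union, size=max_features, replace=False))
    rows = []
    for p in profiles:
        pos = np.searchsorted(union, p.kmers)
        ok = (pos < len(union)) & (union[np.minimum(pos, len(union) - 1)] == p.kmers)
        row = np.zeros(len(union), dtype=np.int8)
        row[pos[ok]] = 1
        rows.append(row)
    return pd.DataFrame(
        np.vstack(rows),
        index=[p.sample_id for p in profiles],
        columns=[f"k{j}" for j in range(len(union))],
    )


def _check_table(table: pd.DataFrame) -> np.ndarray:
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("table entries must be non-negative")
    return x


def jaccard_dissimilarity(table: pd.DataFrame) -> DissimilarityMatrix:
    """Presence/absence Jaccard dissimilarity, ``100 (b+c) / (a+b+c)``.

    ``table`` is samples x features; entries > 0 mark presence.
    """
    x = _check_table(table) > 0
    if (~x.any(axis=1)).any():
        bad = table.index[~x.any(axis=1)].tolist()
        raise ValueError(f"samples with zero present features: {bad}")
    a = (x.astype(np.int64) @ x.T.astype(np.int64)).astype(float)
    sizes = x.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - a
    values = 100.0 * (union - a) / union
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(
        ids=list(table.index.astype(str)), values=values, metric="jaccard"
    )


def bray_curtis_dissimilarity(table: pd.DataFrame) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity, ``100 sum|x-y| / sum(x+y)``, on abundances."""
    x = _check_table(table)
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        bad = table.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total abundance: {bad}")
    n = x.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        values[i, i + 1 :] = 100.0 * diff / (totals[i] + totals[i + 1 :])
    values += values.T
    return DissimilarityMatrix(
        ids=list(table.index.astype(str)), values=values, metric="bray_curtis"
    )
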