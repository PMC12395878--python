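"""Binary and multiset (counted) Tanimoto similarity.

The binary Tanimoto coefficient is T(A, B) = |A ∩ B| / |A ∪ B| on bit
vectors.  Counted fingerprints use its multiset generalisation,

    T_multiset(A, B) = Σ_i min(A_i, B_i) / Σ_i max(A_i, B_i),

which reduces exactly to the binary form on 0/1 vectors.  Similarity
between two all-zero fingerprints is defined as 0.0: an empty fingerprint
is no evidence of shared substructure.  Distance for embeddings is
1 − similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fingerprint import CountFingerprint

__all__ = [
    "SimilarityMatrix",
    "binary_tanimoto",
    "multiset_tanimoto",
    "pairwise_matrix",
]

METRICS = ("binary_tanimoto", "multiset_tanimoto")


def _as_counts(vec) -> np.ndarray:
    if isinstance(vec, CountFingerprint):
        return vec.counts
    return np.asarray(vec)


def binary_tanimoto(a, b) -> float:
    """Jaccard/Tanimoto coefficient of two equal-length 0/1 vectors."""
    a = _as_counts(a) > 0
    b = _as_counts(b) > 0
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def multiset_tanimoto(a, b) -> float:
    """Counted Tanimoto: Σ min(Aᵢ, Bᵢ) / Σ max(Aᵢ, Bᵢ)."""
    a = _as_counts(a)
    b = _as_counts(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("count vectors must be non-negative")
    denom = np.maximum(a, b).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(a, b).sum() / denom)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarity over an ordered molecule set."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match number of ids")
        object.__setattr__(self, "values", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_distance(self) -> np.ndarray:
        """1 − similarity, the distance used for embeddings."""
        return 1.0 - self.values


def pairwise_matrix(
    fps: Sequence[CountFingerprint] | np.ndarray,
    metric: str = "multiset_tanimoto",
    ids: Sequence[str] | None = None,
    block: int = 256,
) -> SimilarityMatrix:
    """Full symmetric similarity matrix over a list of fingerprints.

    Computation is vectorised in row blocks so memory stays proportional to
    ``block * n`` rather than ``n²`` intermediates per pair.

    Raises on fewer than two fingerprints, mixed registry versions, or an
    unknown metric.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if isinstance(fps, np.ndarray):
        counts = np.asarray(fps, dtype=np.int64)
    else:
        fps = list(fps)
        versions = {fp.registry_version for fp in fps if isinstance(fp, CountFingerprint)}
        if len(versions) > 1:
            raise ValueError(f"mixed registry versions: {sorted(versions)}")
        counts = np.stack([_as_counts(fp) for fp in fps])
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least two fingerprints")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if metric == "binary_tanimoto":
        counts = (counts > 0).astype(np.int64)

    values = np.empty((n, n), dtype=float)
    for start in range(0, n, block):
        stop = min(start + block, n)
        chunk = counts[start:stop, None, :]  # (b, 1, k)
        mins = np.minimum(chunk, counts[None, :, :]).sum(axis=2)
        maxs = np.maximum(chunk, counts[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(maxs > 0, mins / maxs, 0.0)
        values[start:stop] = sim
    return SimilarityMatrix(ids=tuple(ids), values=values, metric=metric)
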