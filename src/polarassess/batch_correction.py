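"""Cross-dataset batch correction by unpolarized-centroid translation.

Every query embedding is rigidly translated by (c_ref - c_in), where c_in
is the centroid of the query's designated unpolarized cells and c_ref the
reference unpolarized centroid.  Pairwise distances and embedding-shift
cosines are preserved exactly; when no unpolarized cells are designated the
correction is skipped (identity).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .embeddings_io import EmbeddingMatrix

__all__ = ["CentroidPair", "compute_centroid", "centroid_pair", "adjust_embeddings"]


@dataclass
class CentroidPair:
    """Reference and input unpolarized-cell centroids."""

    c_ref: np.ndarray
    c_in: np.ndarray

    def __post_init__(self) -> None:
        self.c_ref = np.asarray(self.c_ref, dtype=float)
        self.c_in = np.asarray(self.c_in, dtype=float)
        if self.c_ref.shape != self.c_in.shape:
            raise ValueError("centroid vectors must have equal length")
        if not (np.isfinite(self.c_ref).all() and np.isfinite(self.c_in).all()):
            raise ValueError("centroids must be finite")

    @property
    def translation(self) -> np.ndarray:
        return self.c_ref - self.c_in


def compute_centroid(values: np.ndarray, method: str = "mean") -> np.ndarray:
    """Centroid of embedding rows; arithmetic mean by default, median optional."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("need a non-empty 2-d matrix of embeddings")
    if method == "mean":
        return values.mean(axis=0)
    if method == "median":
        return np.median(values, axis=0)
    raise ValueError(f"unknown centroid method {method!r}")


def centroid_pair(
    query: EmbeddingMatrix,
    unpolarized_cell_ids: Sequence[str],
    c_ref: np.ndarray,
    method: str = "mean",
) -> CentroidPair:
    """Build the centroid pair from designated unpolarized query cells."""
    ids = list(unpolarized_cell_ids)
    if not ids:
        raise ValueError("batch correction requested but the unpolarized cell set is empty")
    sub = query.subset(ids)
    return CentroidPair(c_ref=np.asarray(c_ref, float), c_in=compute_centroid(sub.values, method))


def adjust_embeddings(
    query: EmbeddingMatrix, centroids: Optional[CentroidPair]
) -> EmbeddingMatrix:
    """Translate query embeddings onto the reference frame.

    ``centroids=None`` skips correction (identity), for datasets without a
    designated unpolarized population.
    """
    if centroids is None:
        return EmbeddingMatrix(list(query.cell_ids), query.values.copy())
    if query.n_dims != centroids.c_ref.shape[0]:
        raise ValueError(
            f"embedding dimension {query.n_dims} does not match centroid length "
            f"{centroids.c_ref.shape[0]}"
        )
    return EmbeddingMatrix(list(query.cell_ids), query.values + centroids.translation)
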