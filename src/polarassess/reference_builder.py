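"""Selection of fully polarized training cells.

A cell qualifies as fully polarized for a state when (1) it comes from a
sample treated with one of the state's driving cytokines, (2) its mean
marker-gene expression strictly exceeds the chosen percentile of all
same-type cells, and (3) the cosine similarity of its embedding shift
(embedding minus unpolarized centroid) to the shifts of the other
driving-cytokine cells is at least a minimum mean value.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .embeddings_io import CellAnnotations, EmbeddingMatrix, ExpressionMatrix
from .registry import PolarizationState, normalize_cytokine

__all__ = [
    "DEFAULT_MARKER_PERCENTILE",
    "DEFAULT_MIN_MEAN_COSINE",
    "EmbeddingShiftSet",
    "FilterThresholds",
    "unpolarized_centroid",
    "embedding_shifts",
    "mean_cosine_to_group",
    "mean_cosines_leave_one_out",
    "marker_filter",
    "select_fully_polarized",
]

DEFAULT_MARKER_PERCENTILE = 90.0
DEFAULT_MIN_MEAN_COSINE = 0.10

#: range over which per-cell-type cosine thresholds are documented as sensible
COSINE_THRESHOLD_RANGE = (0.08, 0.2)

DEFAULT_CONTROL_LABEL = "PBS"


@dataclass
class EmbeddingShiftSet:
    """Embedding shifts of a set of cells relative to the unpolarized centroid."""

    cell_ids: list[str]
    shifts: np.ndarray  # n x D
    centroid: np.ndarray  # length D

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.shifts.shape != (len(self.cell_ids), self.centroid.shape[0]):
            raise ValueError("shift matrix shape does not match cell ids / centroid")


@dataclass
class FilterThresholds:
    """Thresholds for the fully-polarized-cell filters.

    ``min_mean_cosine`` may be overridden per cell type via
    ``min_mean_cosine_per_type``.
    """

    marker_percentile: float = DEFAULT_MARKER_PERCENTILE
    min_mean_cosine: float = DEFAULT_MIN_MEAN_COSINE
    min_mean_cosine_per_type: dict[str, float] = field(default_factory=dict)
    control_label: str = DEFAULT_CONTROL_LABEL

    def __post_init__(self) -> None:
        if not (0 <= self.marker_percentile <= 100):
            raise ValueError("marker_percentile must be in [0, 100]")
        if not (-1 <= self.min_mean_cosine <= 1):
            raise ValueError("min_mean_cosine must be in [-1, 1]")

    def min_cosine_for(self, cell_type: str) -> float:
        return self.min_mean_cosine_per_type.get(cell_type, self.min_mean_cosine)


def unpolarized_centroid(
    embeddings: EmbeddingMatrix,
    annotations: CellAnnotations,
    control_label: str = DEFAULT_CONTROL_LABEL,
    cell_type: Optional[str] = None,
) -> np.ndarray:
    """Arithmetic mean embedding of control-treated cells (of one type if given)."""
    ann = annotations.aligned_to(embeddings).table
    key = normalize_cytokine(control_label)
    mask = ann["treatment"].map(normalize_cytokine) == key
    if cell_type is not None:
        mask &= ann["cell_type"].str.casefold() == cell_type.casefold()
    if not mask.any():
        raise ValueError(
            f"no control cells with treatment {control_label!r}"
            + (f" for cell type {cell_type!r}" if cell_type else "")
        )
    return embeddings.values[np.asarray(mask)].mean(axis=0)


def embedding_shifts(
    embeddings: EmbeddingMatrix, centroid: np.ndarray, cell_ids: Optional[Sequence[str]] = None
) -> EmbeddingShiftSet:
    """Shift of each cell's embedding relative to the unpolarized centroid."""
    sub = embeddings if cell_ids is None else embeddings.subset(list(cell_ids))
    return EmbeddingShiftSet(
        cell_ids=list(sub.cell_ids),
        shifts=sub.values - np.asarray(centroid, float),
        centroid=np.asarray(centroid, float),
    )


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-length embedding shift(s); cosine defined as 0",
            stacklevel=3,
        )
    safe = np.where(norms == 0, 1.0, norms)
    out = x / safe
    out[zero] = 0.0
    return out


def mean_cosine_to_group(
    shift: np.ndarray, group_shifts: np.ndarray, exclude_index: Optional[int] = None
) -> float:
    """Mean cosine similarity of *shift* to the rows of *group_shifts*.

    ``exclude_index`` removes the cell's own row when it is part of the group
    (leave-one-out).  Zero-length vectors contribute similarity 0.
    """
    group = np.asarray(group_shifts, dtype=float)
    if group.ndim != 2 or group.shape[0] == 0:
        raise ValueError("group_shifts must be a non-empty 2-d matrix")
    if exclude_index is not None:
        if group.shape[0] == 1:
            raise ValueError("group is empty after excluding the cell itself")
        group = np.delete(group, exclude_index, axis=0)
    u = _unit_rows(np.asarray(shift, float)[None, :])[0]
    g = _unit_rows(group)
    return float(np.mean(g @ u))


def mean_cosines_leave_one_out(shifts: np.ndarray) -> np.ndarray:
    """For each row, mean cosine similarity to all *other* rows (vectorized)."""
    shifts = np.asarray(shifts, dtype=float)
    m = shifts.shape[0]
    if m < 2:
        raise ValueError("need at least two shift vectors for leave-one-out cosines")
    u = _unit_rows(shifts)
    total = u.sum(axis=0)
    self_sim = np.einsum("ij,ij->i", u, u)  # 1 for nonzero rows, 0 for zero rows
    return (u @ total - self_sim) / (m - 1)


def marker_filter(
    expression: ExpressionMatrix,
    cells_of_type: Sequence[str],
    candidate_cells: Sequence[str],
    marker_genes: Sequence[str],
    percentile: float = DEFAULT_MARKER_PERCENTILE,
) -> np.ndarray:
    """Boolean mask over candidates passing the marker-expression criterion.

    A candidate passes iff its mean marker expression strictly exceeds the
    *percentile*-th empirical percentile (linear interpolation between order
    statistics) of mean marker expression over all same-type cells.
    """
    if not marker_genes:
        raise ValueError("marker_genes must be non-empty")
    type_means = expression.mean_over_genes(list(marker_genes), list(cells_of_type))
    cand_means = expression.mean_over_genes(list(marker_genes), list(candidate_cells))
    cutoff = np.percentile(type_means, percentile)
    return cand_means > cutoff


def select_fully_polarized(
    state: PolarizationState,
    embeddings: EmbeddingMatrix,
    annotations: CellAnnotations,
    expression: ExpressionMatrix,
    thresholds: Optional[FilterThresholds] = None,
) -> set[str]:
    """Cells of *state*'s type satisfying all three fully-polarized criteria."""
    thresholds = thresholds or FilterThresholds()
    ann = annotations.aligned_to(embeddings).table
    type_mask = ann["cell_type"].str.casefold() == state.cell_type.casefold()
    type_ids = list(ann.index[type_mask])
    if not type_ids:
        warnings.warn(f"no cells of type {state.cell_type!r} for state {state.state_id}")
        return set()

    treatments = ann["treatment"].map(normalize_cytokine)
    driving = {normalize_cytokine(c) for c in state.driving_cytokines}
    crit1_mask = type_mask & treatments.isin(driving)
    crit1_ids = list(ann.index[crit1_mask])
    if not crit1_ids:
        warnings.warn(
            f"state {state.state_id}: no cells treated with a driving cytokine "
            f"({', '.join(state.driving_cytokines)})"
        )
        return set()

    centroid = unpolarized_centroid(
        embeddings, annotations, thresholds.control_label, cell_type=state.cell_type
    )

    selected: set[str]
    if len(crit1_ids) == 1:
        # no group to compare against; cosine criterion vacuously passes
        cosine_ok = np.array([True])
    else:
        shifts = embedding_shifts(embeddings, centroid, crit1_ids).shifts
        cosines = mean_cosines_leave_one_out(shifts)
        cosine_ok = cosines >= thresholds.min_cosine_for(state.cell_type)

    marker_ok = marker_filter(
        expression,
        type_ids,
        crit1_ids,
        list(state.marker_genes),
        thresholds.marker_percentile,
    )

    selected = {cid for cid, m, c in zip(crit1_ids, marker_ok, cosine_ok) if m and c}
    if not selected:
        warnings.warn(f"state {state.state_id}: no fully polarized cells found (untrainable)")
    return selected
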