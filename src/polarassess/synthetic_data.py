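"""Synthetic fixture datasets with the statistical structure the method assumes.

Each cell type is a Gaussian cluster in embedding space.  Treated arms add a
state-specific mean shift to a *fraction* of their cells (partial response);
marker genes are elevated only in the shifted cells.  Additional "bystander"
cytokine arms carry no planted state, mirroring a reference where most
treatments do not drive any given state, so planted responders are a small
minority of each cell type.  A query generator adds a constant batch offset,
and an interpolator builds intermediate-polarization cells as convex
combinations of sampled unpolarized and polarized cells.

Embeddings are quantized to a dyadic grid (2^-20 by default) so that the
batch-correction translation cancels exactly in floating point when arm
sizes are powers of two.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embeddings_io import CellAnnotations, EmbeddingMatrix, ExpressionMatrix
from .registry import PolarizationState, Registry

__all__ = [
    "StateSpec",
    "SyntheticSpec",
    "SyntheticDataset",
    "default_spec",
    "build_registry",
    "generate_reference",
    "generate_query_with_batch",
    "interpolate_cells",
]

DEFAULT_BYSTANDER_CYTOKINES = (
    "IL-6", "IL-10", "TGF-β", "IL-17A", "GM-CSF", "IL-33", "IL-36α", "TSLP",
)

_LETTER_CYTOKINES = {"a": "IFN-β", "b": "IFN-γ", "c": "IL-1β", "d": "TNF-α"}

_TYPE_ABBREV = {
    "Macrophage": "Mac",
    "CD8 T cell": "T8",
    "NK cell": "NK",
    "B cell": "B",
    "Monocyte": "Mono",
}


@dataclass(frozen=True)
class StateSpec:
    """One planted polarization state: shift direction, magnitude, markers."""

    state_id: str
    cell_type: str
    treatment: str
    direction: tuple[float, ...]  # unit vector, length D
    magnitude: float = 5.0
    marker_genes: tuple[str, ...] = ()
    marker_effect: float = 3.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("shift magnitude must be >= 0")


@dataclass
class SyntheticSpec:
    """Full parameterization of a synthetic reference dataset."""

    seed: int
    n_dims: int = 16
    noise_sd: float = 1.0
    fraction_responding: float = 0.5
    n_per_arm: int = 200
    cell_type_means: dict[str, tuple[float, ...]] = field(default_factory=dict)
    states: list[StateSpec] = field(default_factory=list)
    bystander_cytokines: tuple[str, ...] = DEFAULT_BYSTANDER_CYTOKINES
    control_label: str = "PBS"
    n_background_genes: int = 20
    marker_baseline_sigma: float = 0.7
    quantize_bits: Optional[int] = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.fraction_responding <= 1):
            raise ValueError("fraction_responding must be in [0, 1]")
        for st in self.states:
            if st.cell_type not in self.cell_type_means:
                raise ValueError(f"state {st.state_id} references unknown cell type")
            if len(st.direction) != self.n_dims:
                raise ValueError(f"state {st.state_id} direction has wrong dimension")
        # a treated arm is keyed by its cytokine: one planted state per arm
        for ct in self.cell_type_means:
            treats = [s.treatment for s in self.states if s.cell_type == ct]
            if len(treats) != len(set(treats)):
                raise ValueError(f"cell type {ct!r} has states sharing a treatment")
        drivers = {s.treatment for s in self.states}
        if drivers & set(self.bystander_cytokines):
            raise ValueError("bystander cytokines must not overlap driving cytokines")


@dataclass
class SyntheticDataset:
    """Generated dataset plus ground truth and a matching registry."""

    embeddings: EmbeddingMatrix
    annotations: CellAnnotations
    expression: ExpressionMatrix
    truth: dict[str, set[str]]  # state_id -> fully polarized cell ids
    registry: Registry
    spec: SyntheticSpec


def _quantize(values: np.ndarray, bits: Optional[int]) -> np.ndarray:
    if bits is None:
        return values
    scale = float(2**bits)
    return np.round(values * scale) / scale


def default_spec(
    seed: int,
    n_dims: int = 16,
    n_cell_types: int = 3,
    states_per_type: int = 2,
    n_per_arm: int = 200,
    **overrides,
) -> SyntheticSpec:
    """Convenience builder: Gaussian cell-type clusters with planted states.

    Cell types get well-separated base means; each state gets a random unit
    shift direction and three dedicated marker genes.
    """
    if n_cell_types > len(_TYPE_ABBREV):
        raise ValueError(f"at most {len(_TYPE_ABBREV)} default cell types")
    if states_per_type > len(_LETTER_CYTOKINES):
        raise ValueError(f"at most {len(_LETTER_CYTOKINES)} default states per type")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    cell_types = list(_TYPE_ABBREV)[:n_cell_types]
    means = {ct: tuple(rng.normal(0.0, 3.0, n_dims)) for ct in cell_types}
    states: list[StateSpec] = []
    for ct in cell_types:
        for letter in list(_LETTER_CYTOKINES)[:states_per_type]:
            d = rng.normal(0.0, 1.0, n_dims)
            d /= np.linalg.norm(d)
            sid = f"{_TYPE_ABBREV[ct]}-{letter}"
            states.append(
                StateSpec(
                    state_id=sid,
                    cell_type=ct,
                    treatment=_LETTER_CYTOKINES[letter],
                    direction=tuple(d),
                    marker_genes=tuple(f"{sid}.M{i}" for i in range(1, 4)),
                )
            )
    return SyntheticSpec(
        seed=seed, n_dims=n_dims, n_per_arm=n_per_arm,
        cell_type_means=means, states=states, **overrides,
    )


def build_registry(spec: SyntheticSpec) -> Registry:
    """Registry describing exactly the states planted by *spec*."""
    states = [
        PolarizationState(
            state_id=s.state_id,
            cell_type=s.cell_type,
            driving_cytokines=(s.treatment,),
            marker_genes=s.marker_genes,
        )
        for s in spec.states
    ]
    return Registry(states=states)


def generate_reference(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a labeled reference dataset from *spec* (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_arm
    cell_ids: list[str] = []
    rows: list[np.ndarray] = []
    ann_rows: list[dict] = []
    truth: dict[str, set[str]] = {s.state_id: set() for s in spec.states}
    responder_cols: dict[str, list[int]] = {s.state_id: [] for s in spec.states}

    for ct, mean in spec.cell_type_means.items():
        mean = np.asarray(mean, dtype=float)
        type_states = [s for s in spec.states if s.cell_type == ct]
        arms: list[tuple[str, Optional[StateSpec]]] = [(spec.control_label, None)]
        arms += [(s.treatment, s) for s in type_states]
        arms += [(c, None) for c in spec.bystander_cytokines]
        for treatment, state in arms:
            block = mean + rng.normal(0.0, spec.noise_sd, (n, spec.n_dims))
            ids = [f"{ct}|{treatment}|{i}" for i in range(n)]
            if state is not None:
                n_resp = int(round(spec.fraction_responding * n))
                resp = rng.choice(n, size=n_resp, replace=False)
                block[resp] += state.magnitude * np.asarray(state.direction)
                base = len(cell_ids)
                truth[state.state_id] = {ids[i] for i in resp}
                responder_cols[state.state_id] = [base + int(i) for i in resp]
            cell_ids.extend(ids)
            rows.append(block)
            ann_rows.extend(
                {
                    "cell_id": cid,
                    "cell_type": ct,
                    "sample_id": f"{ct}_{treatment}",
                    "treatment": treatment,
                }
                for cid in ids
            )

    values = _quantize(np.vstack(rows), spec.quantize_bits)
    embeddings = EmbeddingMatrix(cell_ids, values)
    ann = CellAnnotations(pd.DataFrame(ann_rows).set_index("cell_id"))

    genes = [g for s in spec.states for g in s.marker_genes]
    genes += [f"BG{i}" for i in range(spec.n_background_genes)]
    expr = rng.lognormal(0.0, spec.marker_baseline_sigma, (len(genes), len(cell_ids)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for s in spec.states:
        cols = responder_cols[s.state_id]
        if cols:
            for g in s.marker_genes:
                expr[gene_index[g], cols] += s.marker_effect
    expr = np.maximum(expr, 0.0)  # lognormal + positive effect; clamp documents intent
    expression = ExpressionMatrix(genes, list(cell_ids), expr)

    return SyntheticDataset(
        embeddings=embeddings,
        annotations=ann,
        expression=expression,
        truth=truth,
        registry=build_registry(spec),
        spec=spec,
    )


def generate_query_with_batch(
    spec: SyntheticSpec, offset: np.ndarray
) -> tuple[SyntheticDataset, list[str]]:
    """Reference-like query translated by a constant batch *offset*.

    Returns the dataset and the control-cell ids to designate as unpolarized
    for correction.  The offset is quantized to the spec's dyadic grid so the
    translation cancels exactly downstream.
    """
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (spec.n_dims,):
        raise ValueError(f"offset must have length {spec.n_dims}")
    ds = generate_reference(spec)
    offset = _quantize(offset, spec.quantize_bits)
    shifted = EmbeddingMatrix(list(ds.embeddings.cell_ids), ds.embeddings.values + offset)
    ds = replace(ds, embeddings=shifted)
    ann = ds.annotations.table
    ctrl = ann.index[ann["treatment"] == spec.control_label]
    return ds, list(ctrl)


def interpolate_cells(
    unpolarized: np.ndarray,
    polarized: np.ndarray,
    t: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """n synthetic cells, each (1-t)*u + t*p with u, p sampled with replacement."""
    unpolarized = np.atleast_2d(np.asarray(unpolarized, dtype=float))
    polarized = np.atleast_2d(np.asarray(polarized, dtype=float))
    if unpolarized.shape[0] == 0 or polarized.shape[0] == 0:
        raise ValueError("both cell pools must be non-empty")
    if not (0 <= t <= 1):
        raise ValueError("polarization level t must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = rng.integers(0, unpolarized.shape[0], size=n)
    ip = rng.integers(0, polarized.shape[0], size=n)
    return (1 - t) * unpolarized[iu] + t * polarized[ip]
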