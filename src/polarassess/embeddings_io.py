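"""I/O for cell embeddings, annotations and expression, plus per-cell-type PCA.

Embeddings are dense ``n_cells x D`` matrices (D nominally 1280 for
foundation-model embeddings); classifiers operate on the top-K principal
components fit per cell type (K defaults to 20).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EXPECTED_EMBEDDING_DIM",
    "DEFAULT_N_COMPONENTS",
    "EmbeddingMatrix",
    "CellAnnotations",
    "ExpressionMatrix",
    "PCBasis",
    "DataError",
    "read_dataset",
    "write_dataset",
    "read_embeddings_tsv",
    "read_annotations_tsv",
    "read_expression_tsv",
    "validate_embedding_dim",
    "fit_pc_basis",
    "project",
]

#: Width of foundation-model cell embeddings accepted by the strict validator.
EXPECTED_EMBEDDING_DIM = 1280

#: Default number of principal components used as classifier features.
DEFAULT_N_COMPONENTS = 20

ANNOTATION_COLUMNS = ("cell_type", "sample_id", "treatment")

#: obsm slot holding the embeddings in an h5ad container.
H5_EMBEDDING_SLOT = "X_uce"


class DataError(ValueError):
    """Malformed or inconsistent input dataset."""


@dataclass
class EmbeddingMatrix:
    """Per-cell embedding vectors keyed by unique cell ids."""

    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataError("embedding values must be a 2-d matrix")
        if self.values.shape[0] != len(self.cell_ids):
            raise DataError(
                f"{len(self.cell_ids)} cell ids but {self.values.shape[0]} embedding rows"
            )
        if self.values.shape[0] < 1:
            raise DataError("embedding matrix must contain at least one cell")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = pd.Index(self.cell_ids)
            raise DataError(
                f"duplicate cell ids: {sorted(dupes[dupes.duplicated()])[:5]}"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            offender = self.cell_ids[int(np.where(bad.any(axis=1))[0][0])]
            raise DataError(f"non-finite embedding values (first offending cell: {offender!r})")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def subset(self, cell_ids: list[str]) -> "EmbeddingMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            rows = [index[c] for c in cell_ids]
        except KeyError as exc:
            raise DataError(f"cell id {exc.args[0]!r} not in embedding matrix") from exc
        return EmbeddingMatrix(list(cell_ids), self.values[rows])


@dataclass
class CellAnnotations:
    """Per-cell metadata: cell type, sample, and treatment labels."""

    table: pd.DataFrame  # indexed by cell_id

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"annotations missing required column(s) {missing}")
        if self.table.index.has_duplicates:
            raise DataError("annotations contain duplicate cell ids")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, embeddings: EmbeddingMatrix) -> "CellAnnotations":
        """Reorder to match *embeddings*; error on cells without annotations."""
        missing = [c for c in embeddings.cell_ids if c not in self.table.index]
        if missing:
            raise DataError(
                f"{len(missing)} cell(s) have embeddings but no annotations "
                f"(first: {missing[0]!r})"
            )
        return CellAnnotations(self.table.loc[embeddings.cell_ids])


@dataclass
class ExpressionMatrix:
    """Dense gene x cell normalized-expression matrix (non-negative)."""

    genes: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cell_ids)):
            raise DataError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene symbols in expression matrix")
        if not np.isfinite(self.values).all():
            raise DataError("non-finite expression values")

    def mean_over_genes(self, genes: list[str], cell_ids: list[str]) -> np.ndarray:
        """Mean expression of *genes* per requested cell."""
        gindex = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in gindex]
        if missing:
            raise DataError(f"marker gene(s) not found in expression matrix: {missing}")
        cindex = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            cols = [cindex[c] for c in cell_ids]
        except KeyError as exc:
            raise DataError(f"cell id {exc.args[0]!r} not in expression matrix") from exc
        rows = [gindex[g] for g in genes]
        return self.values[np.ix_(rows, cols)].mean(axis=0)


@dataclass
class PCBasis:
    """Per-cell-type centering vector and orthonormal top-K loadings."""

    cell_type: str
    center: np.ndarray
    loadings: np.ndarray  # D x K, columns orthonormal
    explained_variance: np.ndarray  # length K, non-increasing

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.loadings.shape[0] != self.center.shape[0]:
            raise DataError("loadings rows must match center length")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise DataError("loadings columns are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise DataError("explained_variance must be non-increasing")
        if np.any(self.explained_variance < -1e-12):
            raise DataError("explained_variance must be non-negative")

    @property
    def n_dims(self) -> int:
        return self.center.shape[0]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


# ---------------------------------------------------------------------------
# readers / writers


def read_embeddings_tsv(path: str | Path) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return EmbeddingMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def read_annotations_tsv(path: str | Path) -> CellAnnotations:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return CellAnnotations(df)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ExpressionMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float)
    )


def read_dataset(
    path: str | Path, format: str = "tsv"
) -> tuple[EmbeddingMatrix, CellAnnotations, Optional[ExpressionMatrix]]:
    """Read an aligned (embeddings, annotations, expression) dataset.

    ``tsv``: *path* is a directory containing ``embeddings.tsv`` and
    ``annotations.tsv`` (and optionally ``expression.tsv``), sharing cell ids.
    ``h5-container``: *path* is an AnnData ``.h5ad`` file with embeddings in
    ``obsm["X_uce"]``, annotation columns in ``obs``, and expression in ``X``.
    """
    path = Path(path)
    if format == "tsv":
        emb = read_embeddings_tsv(path / "embeddings.tsv")
        ann = read_annotations_tsv(path / "annotations.tsv")
        expr_path = path / "expression.tsv"
        expr = read_expression_tsv(expr_path) if expr_path.exists() else None
    elif format == "h5-container":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if H5_EMBEDDING_SLOT not in adata.obsm:
            raise DataError(f"h5 container has no obsm slot {H5_EMBEDDING_SLOT!r}")
        cell_ids = list(adata.obs_names.astype(str))
        emb = EmbeddingMatrix(cell_ids, np.asarray(adata.obsm[H5_EMBEDDING_SLOT], dtype=float))
        missing = [c for c in ANNOTATION_COLUMNS if c not in adata.obs.columns]
        if missing:
            raise DataError(f"annotations missing required column(s) {missing}")
        ann = CellAnnotations(adata.obs[list(ANNOTATION_COLUMNS)].astype(str))
        expr = None
        if adata.X is not None and adata.n_vars > 0:
            X = adata.X
            if hasattr(X, "toarray"):
                X = X.toarray()
            expr = ExpressionMatrix(
                list(adata.var_names.astype(str)), cell_ids, np.asarray(X, dtype=float).T
            )
    else:
        raise ValueError(f"unknown dataset format {format!r}")
    ann = ann.aligned_to(emb)
    if expr is not None:
        missing = [c for c in emb.cell_ids if c not in set(expr.cell_ids)]
        if missing:
            raise DataError(
                f"{len(missing)} cell(s) missing from expression matrix (first: {missing[0]!r})"
            )
    return emb, ann, expr


def _fmt(v: float) -> str:
    return f"{v:.17g}"


def write_dataset(
    out_dir: str | Path,
    embeddings: EmbeddingMatrix,
    annotations: CellAnnotations,
    expression: Optional[ExpressionMatrix] = None,
) -> None:
    """Write the tsv form read by :func:`read_dataset` (lossless for doubles)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "embeddings.tsv", "w", encoding="utf-8") as fh:
        d = embeddings.n_dims
        fh.write("cell_id\t" + "\t".join(f"dim_{j}" for j in range(d)) + "\n")
        for cid, row in zip(embeddings.cell_ids, embeddings.values):
            fh.write(cid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    annotations.table.to_csv(out / "annotations.tsv", sep="\t", index_label="cell_id")
    if expression is not None:
        with open(out / "expression.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\t" + "\t".join(expression.cell_ids) + "\n")
            for g, row in zip(expression.genes, expression.values):
                fh.write(g + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# PCA


def validate_embedding_dim(
    matrix: EmbeddingMatrix, expected: int = EXPECTED_EMBEDDING_DIM, strict: bool = False
) -> str:
    """Check embedding width against the expected foundation-model width.

    Returns ``"pass"`` or ``"warn"``; in strict mode a mismatch raises.
    """
    if matrix.n_dims == expected:
        return "pass"
    msg = f"embedding dimension is {matrix.n_dims}, expected {expected}"
    if strict:
        raise DataError(msg)
    warnings.warn(msg, stacklevel=2)
    return "warn"


def fit_pc_basis(
    matrix: EmbeddingMatrix | np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    cell_type: str = "",
) -> PCBasis:
    """Fit a mean-centered PCA basis with a deterministic sign convention.

    Loadings are the top-K right singular directions of the centered matrix;
    each column is flipped so its largest-magnitude element is positive.
    K is clamped to the embedding dimension when D < K.
    """
    values = matrix.values if isinstance(matrix, EmbeddingMatrix) else np.asarray(matrix, float)
    n, d = values.shape
    k = int(n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if k > d:
        warnings.warn(
            f"n_components={k} exceeds embedding dimension {d}; clamping to {d}",
            stacklevel=2,
        )
        k = d
    if n <= k:
        raise DataError(
            f"need more than {k} cells to fit {k} components (got {n}); use a smaller K"
        )
    center = values.mean(axis=0)
    _, s, vt = np.linalg.svd(values - center, full_matrices=False)
    loadings = vt[:k].T.copy()
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    explained = s[:k] ** 2 / (n - 1)
    return PCBasis(cell_type=cell_type, center=center, loadings=loadings, explained_variance=explained)


def project(matrix: EmbeddingMatrix | np.ndarray, basis: PCBasis) -> np.ndarray:
    """Project cells onto a fitted basis: ``(values - center) @ loadings``."""
    values = matrix.values if isinstance(matrix, EmbeddingMatrix) else np.asarray(matrix, float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != basis.n_dims:
        raise DataError(
            f"embedding dimension {values.shape[1]} does not match basis dimension {basis.n_dims}"
        )
    return (values - basis.center) @ basis.loadings
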