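"""End-to-end orchestration: build a reference bundle, assess query datasets.

``build_reference`` fits, per cell type, a PCA basis and the unpolarized
centroid, then per state selects fully polarized cells, trains the scorer
and cross-calibrates conformal quantiles.  ``assess_dataset`` applies the
bundle to new cells: optional centroid batch correction, projection onto
the reference basis, scoring and four-way class prediction.
"""
from __future__ import annotations

import io
import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .batch_correction import CentroidPair, adjust_embeddings, centroid_pair
from .conformal import (
    DEFAULT_ALPHA,
    DEFAULT_FOLDS,
    ConformalCalibration,
    classify_array,
    conformal_quantile,
    cross_calibrate,
)
from .embeddings_io import (
    DEFAULT_N_COMPONENTS,
    CellAnnotations,
    EmbeddingMatrix,
    ExpressionMatrix,
    PCBasis,
    fit_pc_basis,
    project,
)
from .polarization_models import (
    HoldoutResult,
    LabeledFeatureSet,
    TrainedStateModel,
    evaluate_repeated_holdout,
    polarization_score,
    train_state_model,
)
from .reference_builder import FilterThresholds, select_fully_polarized, unpolarized_centroid
from .registry import Registry, load_registry, normalize_cytokine, states_for, write_registry
from .synthetic_data import interpolate_cells

__all__ = [
    "BuildConfig",
    "StateEntry",
    "ReferenceBundle",
    "build_reference",
    "assess_dataset",
    "simulate_trajectory_assessment",
    "benchmark_bundle",
]

RESULT_COLUMNS = ("cell_id", "cell_type", "state_id", "score", "class", "alpha")

DEFAULT_STORED_ALPHAS = (0.01, 0.05, 0.1)


@dataclass
class BuildConfig:
    """Configuration for building a reference bundle."""

    n_components: int = DEFAULT_N_COMPONENTS
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    kind: str = "svm_linear"
    seed: int = 0
    folds: int = DEFAULT_FOLDS
    alphas: tuple[float, ...] = DEFAULT_STORED_ALPHAS
    # synthetic-mode escape hatch: explicit polarized cell ids per state,
    # bypassing the marker/cosine filters (no expression matrix needed)
    ground_truth_polarized: Optional[Mapping[str, Sequence[str]]] = None


@dataclass
class StateEntry:
    """Trained model and calibration for one state, plus its training data."""

    state_id: str
    cell_type: str
    model: TrainedStateModel
    calibration: ConformalCalibration
    features: np.ndarray
    labels: np.ndarray


@dataclass
class ReferenceBundle:
    """Everything needed to assess polarization in new datasets."""

    registry: Registry
    pc_bases: dict[str, PCBasis]  # per cell type
    centroids: dict[str, np.ndarray]  # per cell type, reference unpolarized c_ref
    states: dict[str, StateEntry]  # per state_id
    config: BuildConfig
    build_report: list[dict] = field(default_factory=list)
    version: str = _version

    def __post_init__(self) -> None:
        for entry in self.states.values():
            if entry.cell_type not in self.pc_bases:
                raise ValueError(f"state {entry.state_id} has no PC basis for its cell type")
            if entry.cell_type not in self.centroids:
                raise ValueError(f"state {entry.state_id} has no reference centroid")

    @property
    def cell_types(self) -> list[str]:
        return list(self.pc_bases)

    def states_of_type(self, cell_type: str) -> list[StateEntry]:
        key = cell_type.casefold()
        return [e for e in self.states.values() if e.cell_type.casefold() == key]

    # -- serialization: JSON metadata + arrays in a single npz container ----

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        reg_buf = io.StringIO()
        _write_registry_text(self.registry, reg_buf)
        meta = {
            "version": self.version,
            "registry_tsv": reg_buf.getvalue(),
            "config": {
                "n_components": self.config.n_components,
                "kind": self.config.kind,
                "seed": self.config.seed,
                "folds": self.config.folds,
                "alphas": list(self.config.alphas),
                "thresholds": {
                    "marker_percentile": self.config.thresholds.marker_percentile,
                    "min_mean_cosine": self.config.thresholds.min_mean_cosine,
                    "min_mean_cosine_per_type": self.config.thresholds.min_mean_cosine_per_type,
                    "control_label": self.config.thresholds.control_label,
                },
            },
            "build_report": self.build_report,
            "cell_types": list(self.pc_bases),
            "states": [],
        }
        for ct, basis in self.pc_bases.items():
            arrays[f"pca::{ct}::center"] = basis.center
            arrays[f"pca::{ct}::loadings"] = basis.loadings
            arrays[f"pca::{ct}::ev"] = basis.explained_variance
            arrays[f"centroid::{ct}"] = self.centroids[ct]
        for sid, e in self.states.items():
            m = e.model
            meta["states"].append(
                {
                    "state_id": sid,
                    "cell_type": e.cell_type,
                    "kind": m.kind,
                    "intercept": m.intercept,
                    "calib_a": m.calib_a,
                    "calib_b": m.calib_b,
                    "training_meta": m.training_meta,
                    "calibration_folds": e.calibration.folds,
                    "calibration_seed": e.calibration.seed,
                }
            )
            if m.weights is not None:
                arrays[f"state::{sid}::weights"] = m.weights
            else:
                blob = pickle.dumps(m.estimator)
                arrays[f"state::{sid}::estimator"] = np.frombuffer(blob, dtype=np.uint8)
            arrays[f"state::{sid}::snc"] = e.calibration.scores
            arrays[f"state::{sid}::features"] = e.features
            arrays[f"state::{sid}::labels"] = e.labels
        arrays["__meta__"] = np.array(json.dumps(meta))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceBundle":
        with np.load(path, allow_pickle=False) as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads(str(arrays.pop("__meta__")))
        registry = _read_registry_text(meta["registry_tsv"])
        cfg_d = meta["config"]
        config = BuildConfig(
            n_components=cfg_d["n_components"],
            thresholds=FilterThresholds(**cfg_d["thresholds"]),
            kind=cfg_d["kind"],
            seed=cfg_d["seed"],
            folds=cfg_d["folds"],
            alphas=tuple(cfg_d["alphas"]),
        )
        pc_bases = {}
        centroids = {}
        for ct in meta["cell_types"]:
            pc_bases[ct] = PCBasis(
                cell_type=ct,
                center=arrays[f"pca::{ct}::center"],
                loadings=arrays[f"pca::{ct}::loadings"],
                explained_variance=arrays[f"pca::{ct}::ev"],
            )
            centroids[ct] = arrays[f"centroid::{ct}"]
        states = {}
        for sm in meta["states"]:
            sid = sm["state_id"]
            weights = arrays.get(f"state::{sid}::weights")
            estimator = None
            if weights is None:
                estimator = pickle.loads(arrays[f"state::{sid}::estimator"].tobytes())
            model = TrainedStateModel(
                state_id=sid,
                kind=sm["kind"],
                weights=weights,
                intercept=sm["intercept"],
                calib_a=sm["calib_a"],
                calib_b=sm["calib_b"],
                estimator=estimator,
                training_meta=sm["training_meta"],
            )
            calibration = ConformalCalibration(
                state_id=sid,
                scores=arrays[f"state::{sid}::snc"],
                folds=sm["calibration_folds"],
                seed=sm["calibration_seed"],
            )
            states[sid] = StateEntry(
                state_id=sid,
                cell_type=sm["cell_type"],
                model=model,
                calibration=calibration,
                features=arrays[f"state::{sid}::features"],
                labels=arrays[f"state::{sid}::labels"],
            )
        return cls(
            registry=registry,
            pc_bases=pc_bases,
            centroids=centroids,
            states=states,
            config=config,
            build_report=meta["build_report"],
            version=meta["version"],
        )


def _write_registry_text(registry: Registry, buf: io.StringIO) -> None:
    buf.write("state_id\tcell_type\tdriving_cytokines\tmarker_genes\n")
    for s in registry.states:
        buf.write(
            f"{s.state_id}\t{s.cell_type}\t{';'.join(s.driving_cytokines)}\t"
            f"{';'.join(s.marker_genes)}\n"
        )


def _read_registry_text(text: str) -> Registry:
    import csv as _csv

    from .registry import PolarizationState

    reader = _csv.DictReader(io.StringIO(text), delimiter="\t")
    states = [
        PolarizationState(
            state_id=row["state_id"],
            cell_type=row["cell_type"],
            driving_cytokines=tuple(x for x in row["driving_cytokines"].split(";") if x),
            marker_genes=tuple(x for x in row["marker_genes"].split(";") if x),
        )
        for row in reader
    ]
    return Registry(states=states)


def build_reference(
    embeddings: EmbeddingMatrix,
    annotations: CellAnnotations,
    registry: Registry,
    expression: Optional[ExpressionMatrix] = None,
    config: Optional[BuildConfig] = None,
) -> ReferenceBundle:
    """Build a reference bundle from a labeled reference dataset.

    States that cannot be trained (missing driving-cytokine cells, no
    markers, too few polarized cells) are skipped with a recorded reason in
    ``build_report``; an error is raised only when no state is trainable.
    """
    config = config or BuildConfig()
    ann = annotations.aligned_to(embeddings).table
    report: list[dict] = []
    pc_bases: dict[str, PCBasis] = {}
    centroids: dict[str, np.ndarray] = {}
    states: dict[str, StateEntry] = {}

    ann_types = {t.casefold(): t for t in ann["cell_type"].unique()}
    control_key = normalize_cytokine(config.thresholds.control_label)

    for cell_type in registry.cell_types:
        reg_states = states_for(registry, cell_type)
        if cell_type.casefold() not in ann_types:
            report.append({"cell_type": cell_type, "skipped": "not present in reference"})
            continue
        type_mask = ann["cell_type"].str.casefold() == cell_type.casefold()
        type_ids = list(ann.index[type_mask])
        ctrl_mask = type_mask & (ann["treatment"].map(normalize_cytokine) == control_key)
        ctrl_ids = list(ann.index[ctrl_mask])
        if not ctrl_ids:
            report.append({"cell_type": cell_type, "skipped": "no control cells"})
            continue
        type_emb = embeddings.subset(type_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # K may be clamped for low-D fixtures
            basis = fit_pc_basis(type_emb, config.n_components, cell_type=cell_type)
        pc_bases[cell_type] = basis
        c_ref = embeddings.subset(ctrl_ids).values.mean(axis=0)
        centroids[cell_type] = c_ref

        for state in reg_states:
            if config.ground_truth_polarized is not None and (
                state.state_id in config.ground_truth_polarized
            ):
                pol_ids = [str(c) for c in config.ground_truth_polarized[state.state_id]]
            else:
                if expression is None:
                    report.append(
                        {"state_id": state.state_id, "skipped": "no expression matrix and no ground truth"}
                    )
                    continue
                if not state.marker_genes:
                    report.append(
                        {"state_id": state.state_id, "skipped": "no marker genes in registry"}
                    )
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pol_ids = sorted(
                        select_fully_polarized(
                            state, embeddings, annotations, expression, config.thresholds
                        )
                    )
            if not pol_ids:
                report.append({"state_id": state.state_id, "skipped": "no criterion-1 cells"})
                continue
            if len(pol_ids) < 2:
                report.append({"state_id": state.state_id, "skipped": "fewer than 2 polarized cells"})
                continue
            feats = project(embeddings.subset(pol_ids + ctrl_ids), basis)
            labels = np.concatenate([np.ones(len(pol_ids), int), np.zeros(len(ctrl_ids), int)])
            data = LabeledFeatureSet(feats, labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = train_state_model(
                    data, kind=config.kind, seed=config.seed, state_id=state.state_id
                )
                calibration = cross_calibrate(
                    data, kind=config.kind, folds=config.folds, seed=config.seed,
                    state_id=state.state_id,
                )
            states[state.state_id] = StateEntry(
                state_id=state.state_id,
                cell_type=cell_type,
                model=model,
                calibration=calibration,
                features=feats,
                labels=labels,
            )
            report.append(
                {
                    "state_id": state.state_id,
                    "trained": True,
                    "n_polarized": len(pol_ids),
                    "n_unpolarized": len(ctrl_ids),
                }
            )

    if not states:
        raise ValueError("no trainable states in the reference dataset")
    return ReferenceBundle(
        registry=registry,
        pc_bases=pc_bases,
        centroids=centroids,
        states=states,
        config=config,
        build_report=report,
    )


def assess_dataset(
    bundle: ReferenceBundle,
    embeddings: EmbeddingMatrix,
    annotations: CellAnnotations,
    unpolarized_cell_ids: Optional[Sequence[str]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Score and class-label every query cell for every state of its type.

    When ``unpolarized_cell_ids`` is given, embeddings are first translated
    per cell type so the query's unpolarized centroid matches the reference
    one; otherwise no correction is applied.
    """
    ann = annotations.aligned_to(embeddings).table
    bundle_types = {t.casefold(): t for t in bundle.cell_types}
    present = set(ann["cell_type"].str.casefold())
    overlap = present & set(bundle_types)
    if not overlap:
        raise ValueError("no query cell types overlap the reference bundle")
    for t in sorted(present - set(bundle_types)):
        warnings.warn(f"query cell type {t!r} not in reference bundle; cells skipped")

    unpol = set(map(str, unpolarized_cell_ids)) if unpolarized_cell_ids is not None else None
    frames: list[pd.DataFrame] = []
    for key in bundle_types:
        if key not in overlap:
            continue
        cell_type = bundle_types[key]
        type_ids = list(ann.index[ann["cell_type"].str.casefold() == key])
        type_emb = embeddings.subset(type_ids)
        if unpol is not None:
            ids_in = [c for c in type_ids if c in unpol]
            if not ids_in:
                raise ValueError(
                    f"batch correction requested but no designated unpolarized cells "
                    f"of type {cell_type!r}"
                )
            pair = centroid_pair(type_emb, ids_in, bundle.centroids[cell_type])
            type_emb = adjust_embeddings(type_emb, pair)
        feats = project(type_emb, bundle.pc_bases[cell_type])
        for entry in bundle.states_of_type(cell_type):
            scores = polarization_score(entry.model, feats)
            q_hat = conformal_quantile(entry.calibration.scores, alpha)
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": type_ids,
                        "cell_type": cell_type,
                        "state_id": entry.state_id,
                        "score": scores,
                        "class": classify_array(scores, q_hat),
                        "alpha": alpha,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[list(RESULT_COLUMNS)]


def simulate_trajectory_assessment(
    bundle: ReferenceBundle,
    embeddings: EmbeddingMatrix,
    annotations: CellAnnotations,
    state_id: str,
    polarized_cell_ids: Sequence[str],
    levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_per_level: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean score along an interpolated polarization trajectory.

    Simulated cells at level t are convex combinations (1-t)*u + t*p of
    sampled unpolarized (control) and polarized cells of the state's type.
    """
    entry = bundle.states[state_id]
    ann = annotations.aligned_to(embeddings).table
    control_key = normalize_cytokine(bundle.config.thresholds.control_label)
    ctrl_mask = (ann["cell_type"].str.casefold() == entry.cell_type.casefold()) & (
        ann["treatment"].map(normalize_cytokine) == control_key
    )
    unpol_values = embeddings.values[np.asarray(ctrl_mask)]
    pol_values = embeddings.subset(list(polarized_cell_ids)).values
    basis = bundle.pc_bases[entry.cell_type]
    rows = []
    for i, t in enumerate(levels):
        cells = interpolate_cells(unpol_values, pol_values, float(t), n_per_level, seed + i)
        scores = polarization_score(entry.model, project(cells, basis))
        rows.append({"level": float(t), "mean_score": float(scores.mean())})
    return pd.DataFrame(rows)


def benchmark_bundle(
    bundle: ReferenceBundle,
    repeats: int = 20,
    train_frac: float = 0.7,
    kind: Optional[str] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated-holdout AUROC per trained state, from the stored training data."""
    rows = []
    for sid, entry in bundle.states.items():
        data = LabeledFeatureSet(entry.features, entry.labels)
        result = evaluate_repeated_holdout(
            data, repeats=repeats, train_frac=train_frac,
            kind=kind or bundle.config.kind, seed=seed,
        )
        rows.append(
            {
                "state_id": sid,
                "cell_type": entry.cell_type,
                "mean_auroc": result.mean,
                "median_auroc": result.median,
                "n_repeats": repeats,
            }
        )
    return pd.DataFrame(rows)
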