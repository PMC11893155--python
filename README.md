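# polarassess

Unified assessment of cytokine-driven immune-cell polarization from
single-cell foundation-model embeddings.

Given a reference dataset of cytokine-treated vs control cells (per-cell
embedding vectors plus cell-type / sample / treatment annotations and a
normalized expression matrix), `polarassess`:

1. identifies **fully polarized** training cells per polarization state via
   three criteria — driving-cytokine treatment, marker-gene expression above
   the 90th percentile of same-type cells, and a minimum mean cosine
   similarity of the cell's *embedding shift* (embedding minus unpolarized
   centroid) to the other treated cells;
2. fits, per cell type, a mean-centered PCA basis (top 20 components by
   default) and trains a **linear SVM** per state with Platt-calibrated
   probabilities, so every cell receives a polarization score in [0, 1];
3. calibrates **split-conformal** quantiles by stratified 5-fold
   cross-calibration of nonconformity scores |score − label|, yielding a
   four-way class prediction per cell and state: *polarized*, *unpolarized*,
   *intermediate*, or *uncertain* (default error level α = 0.05);
4. transfers to new datasets via **centroid batch correction**: query
   embeddings are rigidly translated by the difference between the reference
   and query unpolarized centroids before projection onto the reference PCA
   basis (no refitting, no anchor-based integration).

A packaged registry catalogs 66 polarization states across 14 immune cell
types with their driving cytokines; a synthetic-data module generates
fixture datasets (Gaussian cell-type clusters, partial treatment response,
planted marker effects, batch offsets, interpolated intermediate cells) so
the whole pipeline is testable without external downloads.

## CLI

```sh
# generate a synthetic fixture dataset (TSVs + ground truth + registry)
polarassess simulate --out-dir sim --seed 3

# build a reference bundle (PCA bases, SVMs, conformal calibration)
polarassess build-ref --embeddings sim/embeddings.tsv \
    --annotations sim/annotations.tsv --expression sim/expression.tsv \
    --registry sim/registry.tsv --out bundle.npz

# score a query dataset (optional centroid batch correction + error level)
polarassess assess --bundle bundle.npz --embeddings sim/embeddings.tsv \
    --annotations sim/annotations.tsv --unpolarized-cells unpol.txt \
    --alpha 0.05 --out scores.tsv

# repeated 70/30 holdout AUROC per state
polarassess benchmark --bundle bundle.npz --repeats 20
```

`scores.tsv` has one row per (cell, applicable state):
`cell_id  cell_type  state_id  score  class  alpha`.

Input formats: tab-separated embeddings (cells × dims), annotations
(`cell_type`, `sample_id`, `treatment`), expression (genes × cells); or an
AnnData `.h5ad` container with embeddings in `obsm["X_uce"]`. Registry TSV
columns: `state_id`, `cell_type`, `driving_cytokines`, `marker_genes`
(`;`-joined lists). `--registry packaged-default` uses the built-in catalog.

## Python API

```python
import polarassess as pa

emb, ann, expr = pa.read_dataset("ref_dir", format="tsv")
registry = pa.load_registry()  # packaged default
bundle = pa.build_reference(emb, ann, registry, expression=expr)
bundle.save("bundle.npz")

q_emb, q_ann, _ = pa.read_dataset("query_dir")
scores = pa.assess_dataset(bundle, q_emb, q_ann, alpha=0.05)
```

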