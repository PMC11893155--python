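import numpy as np
import pandas as pd
import pytest

from polarassess.assess import (
    BuildConfig,
    ReferenceBundle,
    assess_dataset,
    benchmark_bundle,
    build_reference,
    simulate_trajectory_assessment,
)
from polarassess.embeddings_io import CellAnnotations, EmbeddingMatrix
from polarassess.synthetic_data import default_spec, generate_query_with_batch, generate_reference


class TestBuildReference:
    def test_bookkeeping(self, ref_bundle, ref_spec):
        assert len(ref_bundle.pc_bases) == len(ref_spec.cell_type_means) == 3
        assert len(ref_bundle.states) == len(ref_spec.states) == 6
        assert set(ref_bundle.centroids) == set(ref_bundle.pc_bases)

    def test_missing_cytokine_state_skipped(self, ref_dataset):
        from polarassess.registry import PolarizationState, Registry

        reg = ref_dataset.registry
        ghost = PolarizationState("Mac-f", "Macrophage", ("IL-99",), ("Mac-a.M1",))
        reg2 = Registry(states=list(reg.states) + [ghost])
        bundle = build_reference(
            ref_dataset.embeddings, ref_dataset.annotations, reg2,
            expression=ref_dataset.expression, config=BuildConfig(seed=11),
        )
        assert "Mac-f" not in bundle.states
        reasons = {r.get("state_id"): r.get("skipped") for r in bundle.build_report}
        assert reasons["Mac-f"] == "no criterion-1 cells"

    def test_no_trainable_states_errors(self, ref_dataset):
        from polarassess.registry import PolarizationState, Registry

        reg = Registry(states=[PolarizationState("B-a", "B cell", ("IFN-β",), ("g",))])
        with pytest.raises(ValueError, match="no trainable states"):
            build_reference(
                ref_dataset.embeddings, ref_dataset.annotations, reg,
                expression=ref_dataset.expression,
            )

    def test_rebuild_same_seed_identical_scores(self, ref_dataset, ref_bundle):
        rebuilt = build_reference(
            ref_dataset.embeddings, ref_dataset.annotations, ref_dataset.registry,
            expression=ref_dataset.expression, config=BuildConfig(seed=11),
        )
        a = assess_dataset(ref_bundle, ref_dataset.embeddings, ref_dataset.annotations)
        b = assess_dataset(rebuilt, ref_dataset.embeddings, ref_dataset.annotations)
        assert (a["score"].to_numpy() == b["score"].to_numpy()).all()
        assert (a["class"] == b["class"]).all()

    def test_ground_truth_escape_hatch(self, ref_dataset):
        truth = {sid: sorted(ids) for sid, ids in ref_dataset.truth.items()}
        bundle = build_reference(
            ref_dataset.embeddings, ref_dataset.annotations, ref_dataset.registry,
            expression=None,
            config=BuildConfig(seed=11, ground_truth_polarized=truth),
        )
        assert set(bundle.states) == set(truth)


class TestAssessDataset:
    def test_controls_score_low(self, ref_bundle, ref_dataset):
        res = assess_dataset(ref_bundle, ref_dataset.embeddings, ref_dataset.annotations)
        ann = ref_dataset.annotations.table
        ctrl = set(ann.index[ann["treatment"] == "PBS"])
        sub = res[res["cell_id"].isin(ctrl)]
        assert sub["score"].mean() < 0.5
        assert (sub["class"] == "unpolarized").mean() > 0.9

    def test_polarized_score_high(self, ref_bundle, ref_dataset):
        res = assess_dataset(ref_bundle, ref_dataset.embeddings, ref_dataset.annotations)
        for state_id, truth in ref_dataset.truth.items():
            sub = res[(res["state_id"] == state_id) & res["cell_id"].isin(truth)]
            assert sub["score"].mean() > 0.5, state_id
            assert (sub["class"] == "polarized").mean() > 0.9, state_id

    def test_scores_per_applicable_state(self, ref_bundle, ref_dataset):
        res = assess_dataset(ref_bundle, ref_dataset.embeddings, ref_dataset.annotations)
        per_cell = res.groupby("cell_id")["state_id"].count()
        assert set(per_cell.unique()) == {2}  # two states per cell type
        assert res["score"].between(0, 1).all()
        assert list(res.columns) == ["cell_id", "cell_type", "state_id", "score", "class", "alpha"]

    def test_unknown_cell_type_only_errors(self, ref_bundle):
        emb = EmbeddingMatrix(["x"], np.zeros((1, 16)))
        ann = CellAnnotations(
            pd.DataFrame(
                {"cell_type": ["Platelet"], "sample_id": ["s"], "treatment": ["PBS"]},
                index=pd.Index(["x"], name="cell_id"),
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            assess_dataset(ref_bundle, emb, ann)

    def test_unknown_type_mixed_warns_and_skips(self, ref_bundle, ref_dataset):
        emb = ref_dataset.embeddings
        ann = ref_dataset.annotations.table.copy()
        ann.iloc[0, ann.columns.get_loc("cell_type")] = "Platelet"
        with pytest.warns(UserWarning, match="platelet"):
            res = assess_dataset(ref_bundle, emb, CellAnnotations(ann))
        assert ann.index[0] not in set(res["cell_id"])

    def test_batch_correction_requested_but_no_cells(self, ref_bundle, ref_dataset):
        with pytest.raises(ValueError, match="unpolarized"):
            assess_dataset(
                ref_bundle, ref_dataset.embeddings, ref_dataset.annotations,
                unpolarized_cell_ids=["does-not-exist"],
            )

    def test_offset_query_scores_bit_identical(self, pow2_bundle, pow2_dataset, pow2_spec):
        offset = np.random.default_rng(31).normal(0, 10, pow2_spec.n_dims)
        query, unpol = generate_query_with_batch(pow2_spec, offset)
        base = assess_dataset(
            pow2_bundle, pow2_dataset.embeddings, pow2_dataset.annotations,
            unpolarized_cell_ids=unpol,
        )
        corrected = assess_dataset(
            pow2_bundle, query.embeddings, query.annotations,
            unpolarized_cell_ids=unpol,
        )
        assert (base["score"].to_numpy() == corrected["score"].to_numpy()).all()
        assert (base["class"] == corrected["class"]).all()

    def test_uncorrected_offset_degrades(self, pow2_bundle, pow2_dataset, pow2_spec):
        from polarassess.polarization_models import auroc

        offset = np.random.default_rng(31).normal(0, 10, pow2_spec.n_dims)
        query, unpol = generate_query_with_batch(pow2_spec, offset)

        def state_auroc(res):
            sid = "Mac-a"
            truth = pow2_dataset.truth[sid]
            sub = res[res["state_id"] == sid]
            ann = pow2_dataset.annotations.table
            ctrl = set(ann.index[(ann["treatment"] == "PBS") & (ann["cell_type"] == "Macrophage")])
            sub = sub[sub["cell_id"].isin(truth | ctrl)]
            labels = sub["cell_id"].isin(truth).astype(int)
            return auroc(sub["score"].to_numpy(), labels.to_numpy())

        corrected = assess_dataset(
            pow2_bundle, query.embeddings, query.annotations, unpolarized_cell_ids=unpol
        )
        uncorrected = assess_dataset(pow2_bundle, query.embeddings, query.annotations)
        assert state_auroc(uncorrected) < state_auroc(corrected)

    def test_alpha_flows_through(self, ref_bundle, ref_dataset):
        res = assess_dataset(
            ref_bundle, ref_dataset.embeddings, ref_dataset.annotations, alpha=0.01
        )
        assert (res["alpha"] == 0.01).all()


class TestBundleRoundTrip:
    def test_save_load_bit_identical_assessment(self, ref_bundle, ref_dataset, tmp_path):
        path = tmp_path / "bundle.npz"
        ref_bundle.save(path)
        loaded = ReferenceBundle.load(path)
        a = assess_dataset(ref_bundle, ref_dataset.embeddings, ref_dataset.annotations)
        b = assess_dataset(loaded, ref_dataset.embeddings, ref_dataset.annotations)
        assert (a["score"].to_numpy() == b["score"].to_numpy()).all()
        assert (a["class"] == b["class"]).all()
        assert loaded.registry.state_ids == ref_bundle.registry.state_ids
        assert loaded.config.seed == ref_bundle.config.seed

    def test_calibration_preserved(self, ref_bundle, tmp_path):
        path = tmp_path / "bundle.npz"
        ref_bundle.save(path)
        loaded = ReferenceBundle.load(path)
        for sid in ref_bundle.states:
            np.testing.assert_array_equal(
                loaded.states[sid].calibration.scores,
                ref_bundle.states[sid].calibration.scores,
            )


class TestTrajectory:
    def test_monotone_mean_scores(self, ref_bundle, ref_dataset):
        from scipy.stats import spearmanr

        table = simulate_trajectory_assessment(
            ref_bundle, ref_dataset.embeddings, ref_dataset.annotations,
            "Mac-a", sorted(ref_dataset.truth["Mac-a"]),
            levels=(0.0, 0.25, 0.5, 0.75, 1.0), n_per_level=200, seed=0,
        )
        assert (np.diff(table["mean_score"]) > 0).all()
        rho = spearmanr(table["level"], table["mean_score"]).statistic
        assert rho == pytest.approx(1.0)

    def test_endpoints_match_pools(self, ref_bundle, ref_dataset):
        from polarassess.embeddings_io import project
        from polarassess.polarization_models import polarization_score

        truth = sorted(ref_dataset.truth["T8-a"])
        table = simulate_trajectory_assessment(
            ref_bundle, ref_dataset.embeddings, ref_dataset.annotations,
            "T8-a", truth, levels=(0.0, 1.0), n_per_level=500, seed=1,
        )
        entry = ref_bundle.states["T8-a"]
        basis = ref_bundle.pc_bases["CD8 T cell"]
        pol_scores = polarization_score(
            entry.model, project(ref_dataset.embeddings.subset(truth), basis)
        )
        # resampled pools: means agree within Monte-Carlo tolerance
        assert table["mean_score"].iloc[1] == pytest.approx(pol_scores.mean(), abs=0.05)
        ann = ref_dataset.annotations.table
        ctrl = list(ann.index[(ann["treatment"] == "PBS") & (ann["cell_type"] == "CD8 T cell")])
        ctrl_scores = polarization_score(
            entry.model, project(ref_dataset.embeddings.subset(ctrl), basis)
        )
        assert table["mean_score"].iloc[0] == pytest.approx(ctrl_scores.mean(), abs=0.05)


class TestBenchmark:
    def test_holdout_auroc_high_per_state(self, ref_bundle):
        table = benchmark_bundle(ref_bundle, repeats=5, seed=0)
        assert len(table) == 6
        assert (table["mean_auroc"] >= 0.95).all()

    def test_translation_invariance_of_scores(self, pow2_bundle, pow2_dataset, pow2_spec):
        # scoring(adjust(X + v)) == scoring(adjust(X)) with the same flagged cells
        offset = np.random.default_rng(55).normal(0, 4, pow2_spec.n_dims)
        query, unpol = generate_query_with_batch(pow2_spec, offset)
        a = assess_dataset(
            pow2_bundle, pow2_dataset.embeddings, pow2_dataset.annotations,
            unpolarized_cell_ids=unpol,
        )
        b = assess_dataset(
            pow2_bundle, query.embeddings, query.annotations, unpolarized_cell_ids=unpol
        )
        assert (a["score"].to_numpy() == b["score"].to_numpy()).all()
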