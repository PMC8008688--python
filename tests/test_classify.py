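import numpy as np
import pytest

from protgauss.classify import (
    CVConfig,
    MultiLabelDataset,
    assemble_training_set,
    binary_mode_classifier,
    fit_baseline,
    fit_ovr_svm,
    multilabel_stratified_folds,
    nested_cv,
    predict,
    read_label_table,
    write_label_table,
)
from protgauss.errors import ValidationError
from protgauss.kernel import KernelMatrix
from protgauss.metrics import micro_aupr


def _block_kernel(n_a, n_b):
    """Two perfectly separated similarity blocks (within 1, across 0)."""
    n = n_a + n_b
    K = np.zeros((n, n))
    K[:n_a, :n_a] = 1.0
    K[n_a:, n_a:] = 1.0
    ids = [f"s{i}" for i in range(n)]
    return KernelMatrix(row_ids=ids, values=K, alpha=0.3), np.array([1] * n_a + [0] * n_b)


class TestDataset:
    def test_row_without_label_rejected(self):
        with pytest.raises(ValidationError, match="at least one"):
            MultiLabelDataset(ids=["a", "b"], labels=[[1, 0], [0, 0]],
                              label_names=["x", "y"])

    def test_label_table_roundtrip(self, tmp_path):
        ds = MultiLabelDataset(ids=["a", "b"], labels=[[1, 0], [1, 1]], label_names=["end", "dyad"])
        write_label_table(ds, tmp_path / "labels.tsv")
        back = read_label_table(tmp_path / "labels.tsv")
        assert back.ids == ds.ids
        assert back.label_names == ds.label_names
        assert np.array_equal(back.labels, ds.labels)

    def test_non_binary_table_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("id\tend\na\t2\n")
        with pytest.raises(ValidationError, match="row 1"):
            read_label_table(tmp_path / "bad.tsv")


class TestAssembleTrainingSet:
    def test_filtering_arithmetic(self):
        # 195 annotated entries: 28 with no mode, 21 reserved for testing
        ids = [f"tf{i}" for i in range(195)]
        labels = np.zeros((195, 2), dtype=int)
        labels[28:, 0] = 1  # 167 with at least one mode
        test_ids = set(ids[28:49])  # 21 labelled TFs held out
        out = assemble_training_set(ids, labels, ["end", "dyad"], test_ids)
        assert out.n == 146

    def test_no_test_overlap(self):
        ids = ["a", "b", "c"]
        labels = [[1, 0], [0, 1], [1, 1]]
        out = assemble_training_set(ids, labels, ["x", "y"], {"b"})
        assert out.ids == ["a", "c"]


class TestOvrSvm:
    def test_separable_blocks_recover_training_labels(self):
        K, y = _block_kernel(4, 4)
        model = fit_ovr_svm(K, y[:, None], C=1.0)
        pred = predict(model, K)
        assert np.array_equal(pred.predictions.ravel(), y)

    def test_single_class_column_flagged_constant(self):
        K, _ = _block_kernel(3, 3)
        y = np.ones((6, 1), dtype=int)
        model = fit_ovr_svm(K, y)
        assert model.constant_labels == {0: 1}
        pred = predict(model, K)
        assert np.ptp(pred.scores[:, 0]) == 0.0
        assert pred.predictions[:, 0].all()

    def test_kernel_label_misalignment_rejected(self):
        K, _ = _block_kernel(3, 3)
        with pytest.raises(ValidationError):
            fit_ovr_svm(K, np.ones((5, 1), dtype=int))

    def test_predict_row_permutation_permutes_output(self):
        rng = np.random.default_rng(0)
        K, y = _block_kernel(4, 4)
        model = fit_ovr_svm(K, y[:, None])
        Kc = KernelMatrix(row_ids=[f"t{i}" for i in range(8)], col_ids=K.row_ids,
                          values=K.values + rng.normal(0, 0.01, K.values.shape), alpha=0.3)
        base = predict(model, Kc)
        perm = np.array([1, 0, 2, 3, 4, 5, 7, 6])
        Kp = KernelMatrix(row_ids=[Kc.row_ids[i] for i in perm], col_ids=K.row_ids,
                          values=Kc.values[perm], alpha=0.3)
        assert np.allclose(predict(model, Kp).scores, base.scores[perm])

    def test_misaligned_cross_kernel_rejected(self):
        K, y = _block_kernel(3, 3)
        model = fit_ovr_svm(K, y[:, None])
        bad = KernelMatrix(row_ids=["t"], col_ids=list(reversed(K.row_ids)),
                           values=np.zeros((1, 6)), alpha=0.3)
        with pytest.raises(ValidationError, match="aligned"):
            predict(model, bad)


class TestBaselines:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.3, (10, 4)), rng.normal(5, 0.3, (10, 4))])
        y = np.array([1] * 10 + [0] * 10)[:, None]
        return X, y

    @pytest.mark.parametrize(
        "method, grid",
        [
            ("LR", {"estimator__C": [1.0]}),
            ("kNN", {"estimator__n_neighbors": [3]}),
            ("SVM", {"estimator__kernel": ["linear"], "estimator__C": [1.0]}),
            ("RF", {"estimator__n_estimators": [20]}),
        ],
    )
    def test_separable_training_accuracy(self, separable, method, grid):
        X, y = separable
        search = fit_baseline(X, y, method, grid=grid, cv=CVConfig(inner_folds=3, seed=0))
        assert np.array_equal(np.asarray(search.predict(X)).ravel(), y.ravel())

    def test_knn_one_neighbor_memorizes_training_set(self, separable):
        X, _ = separable
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, (20, 1))
        y[0, 0] = 1  # keep at least one positive
        search = fit_baseline(X, y, "kNN", grid={"estimator__n_neighbors": [1]},
                              cv=CVConfig(inner_folds=3, seed=0))
        assert np.array_equal(np.asarray(search.predict(X)).ravel(), y.ravel())

    def test_planted_dataset_beats_prevalence(self, small_planted, small_reps):
        _, _, ds = small_planted
        feats = np.stack([r.mu for r in small_reps])
        search = fit_baseline(feats, ds.labels, "LR", grid={"estimator__C": [1.0]},
                              cv=CVConfig(inner_folds=3, seed=0))
        aupr = micro_aupr(ds.labels, search.decision_function(feats))
        assert 0.0 <= aupr <= 1.0
        assert aupr >= ds.labels.mean()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError, match="unknown baseline"):
            fit_baseline(np.zeros((4, 2)), np.ones((4, 1), dtype=int), "MLP")


class TestFolds:
    def test_partition_covers_each_sample_once(self):
        rng = np.random.default_rng(3)
        Y = rng.integers(0, 2, (20, 3))
        Y[Y.sum(axis=1) == 0, 0] = 1
        assigned = multilabel_stratified_folds(Y, 10, seed=4)
        assert assigned.shape == (20,)
        assert set(assigned) == set(range(10))
        assert np.bincount(assigned).max() <= 3

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        Y = rng.integers(0, 2, (30, 2))
        a1 = multilabel_stratified_folds(Y, 5, seed=7)
        a2 = multilabel_stratified_folds(Y, 5, seed=7)
        assert np.array_equal(a1, a2)

    def test_rare_label_spread_across_folds(self):
        Y = np.zeros((20, 2), dtype=int)
        Y[:, 0] = 1
        Y[:4, 1] = 1  # 4 positives, 4 folds -> one per fold
        assigned = multilabel_stratified_folds(Y, 4, seed=0)
        per_fold = [Y[assigned == f, 1].sum() for f in range(4)]
        assert per_fold == [1, 1, 1, 1]


class TestNestedCV:
    GRID = {"alpha": [0.3], "C": [1.0]}

    def test_each_sample_in_exactly_one_outer_test_fold(self, small_planted, small_reps):
        _, table, ds = small_planted
        cv = CVConfig(outer_folds=10, inner_folds=3, seed=1, grid=self.GRID)
        res = nested_cv(ds, {table.k: small_reps}, cv)
        seen = sorted(i for rec in res["folds"] for i in rec["test_indices"])
        assert seen == list(range(ds.n))

    def test_same_seed_identical_results(self, small_planted, small_reps):
        _, table, ds = small_planted
        cv = CVConfig(outer_folds=5, inner_folds=3, seed=2, grid=self.GRID)
        r1 = nested_cv(ds, {table.k: small_reps}, cv)
        r2 = nested_cv(ds, {table.k: small_reps}, cv)
        assert r1["fold_assignment"] == r2["fold_assignment"]
        assert r1["micro_aupr_mean"] == r2["micro_aupr_mean"]
        assert np.array_equal(r1["pooled"].scores, r2["pooled"].scores)

    def test_strong_planted_signal_recovered(self, small_planted, small_reps):
        _, table, ds = small_planted
        cv = CVConfig(outer_folds=5, inner_folds=3, seed=3,
                      grid={"alpha": [0.3, 1.0], "C": [1.0]})
        res = nested_cv(ds, {table.k: small_reps}, cv)
        assert res["micro_aupr_mean"] >= 0.9

    def test_tuning_blind_to_test_fold_labels(self, small_planted, small_reps):
        # with the fold partition held fixed, permuting one test fold's
        # labels must change reported metrics but not selected hyperparams
        _, table, ds = small_planted
        cv = CVConfig(outer_folds=5, inner_folds=3, seed=4,
                      grid={"alpha": [0.0, 1.0], "C": [0.1, 1.0]})
        assignment = multilabel_stratified_folds(ds.labels, 5, seed=4)
        base = nested_cv(ds, {table.k: small_reps}, cv, fold_assignment=assignment)

        rng = np.random.default_rng(0)
        test0 = np.where(assignment == 0)[0]
        labels2 = ds.labels.copy()
        labels2[test0] = rng.permutation(labels2[test0])
        labels2[labels2.sum(axis=1) == 0, 0] = 1
        ds2 = MultiLabelDataset(ids=ds.ids, labels=labels2, label_names=ds.label_names)
        perm = nested_cv(ds2, {table.k: small_reps}, cv, fold_assignment=assignment)

        assert base["folds"][0]["hyperparams"] == perm["folds"][0]["hyperparams"]
        assert base["folds"][0]["micro_aupr"] != perm["folds"][0]["micro_aupr"]

    def test_fewer_samples_than_folds_rejected(self, small_planted, small_reps):
        _, table, ds = small_planted
        few = ds.subset(range(5))
        cv = CVConfig(outer_folds=10, inner_folds=3, seed=0, grid=self.GRID)
        with pytest.raises(ValidationError):
            nested_cv(few, {table.k: [small_reps[i] for i in range(5)]}, cv)


class TestBinaryModeClassifier:
    def test_unknown_mode_rejected(self, small_planted, small_reps):
        _, table, ds = small_planted
        with pytest.raises(ValidationError, match="unknown binding mode"):
            binary_mode_classifier(ds, "nope", {table.k: small_reps},
                                   CVConfig(outer_folds=3, inner_folds=3))

    def test_all_negative_mode_rejected(self, small_planted, small_reps):
        _, table, ds = small_planted
        labels = ds.labels.copy()
        labels[:, 1] = 0
        labels[:, 0] = 1
        ds2 = MultiLabelDataset(ids=ds.ids, labels=labels, label_names=ds.label_names)
        with pytest.raises(ValidationError, match="no positive"):
            binary_mode_classifier(ds2, ds.label_names[1], {table.k: small_reps},
                                   CVConfig(outer_folds=3, inner_folds=3))

    def test_planted_mode_recovered(self, small_planted, small_reps):
        _, table, ds = small_planted
        cv = CVConfig(outer_folds=5, inner_folds=3, seed=5,
                      grid={"alpha": [0.3], "C": [1.0]})
        res = binary_mode_classifier(ds, ds.label_names[0], {table.k: small_reps}, cv)
        assert res["pooled_micro_aupr"] >= 0.9
        assert -1.0 <= res["pooled_mcc"] <= 1.0
        assert res["confusion"].n == ds.n

    def test_random_scores_aupr_near_prevalence(self):
        # pooled micro-AUPR of uninformative scores concentrates near p
        rng = np.random.default_rng(6)
        p = 0.3
        vals = []
        for _ in range(50):
            y = (rng.random(200) < p).astype(int)
            if y.sum() == 0:
                continue
            vals.append(micro_aupr(y, rng.random(200)))
        assert abs(np.mean(vals) - p) < 0.05
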