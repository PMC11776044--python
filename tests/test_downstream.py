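"""Embedding extraction, downstream classifiers, CV harness, compound tallies."""

import numpy as np
import pytest

from phenocon.downstream import (
    EmbeddingMatrix,
    cross_validate,
    extract_embeddings,
    predict_compound_classes,
    train_mlp,
    train_random_forest,
)
from phenocon.io_data import AnnotationTable, make_splits, primary_label


def _blob_embeddings(n_per_class=20, dim=8, n_classes=2, sep=4.0, seed=0):
    """Linearly separable class blobs with one compound per 4 images."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_classes, dim)) * sep
    X, img, cpd, labels = [], [], [], []
    for k in range(n_classes):
        for i in range(n_per_class):
            X.append(centers[k] + rng.normal(size=dim))
            c = f"k{k}_c{i // 4}"
            img.append(f"{c}_r{i % 4}")
            cpd.append(c)
            labels.append(f"class_{k}")
    return EmbeddingMatrix(img, cpd, np.array(X)), labels


class TestExtractEmbeddings:
    def test_shapes_and_order(self, tiny_model, tiny_preprocessed):
        model, _ = tiny_model
        records, _, _ = tiny_preprocessed
        emb = extract_embeddings(model, records)
        assert emb.features.shape == (len(records), model.config.projector_dim)
        assert emb.image_ids == [r.image_id for r in records]

    def test_duplicate_record_duplicates_row(self, tiny_model, tiny_preprocessed):
        model, _ = tiny_model
        records, _, _ = tiny_preprocessed
        emb = extract_embeddings(model, [records[0], records[0]])
        assert np.array_equal(emb.features[0], emb.features[1])

    def test_empty_input_rejected(self, tiny_model):
        model, _ = tiny_model
        with pytest.raises(ValueError):
            extract_embeddings(model, [])

    def test_csv_round_trip(self, tmp_path):
        emb, _ = _blob_embeddings()
        emb.to_csv(tmp_path / "emb.csv")
        back = EmbeddingMatrix.from_csv(tmp_path / "emb.csv")
        assert back.image_ids == emb.image_ids
        np.testing.assert_allclose(back.features, emb.features, rtol=1e-6)

    def test_trained_embeddings_separate_classes(self, tiny_model, tiny_preprocessed):
        """Within-class cosine similarity must exceed between-class after training."""
        model, _ = tiny_model
        records, _, truth = tiny_preprocessed
        recs = [r for r in records if not r.is_control]
        Z = extract_embeddings(model, recs).features
        classes = np.array([truth[r.compound_id] for r in recs])
        S = Z @ Z.T
        mask = classes[:, None] == classes[None, :]
        np.fill_diagonal(mask, False)
        off = ~np.eye(len(Z), dtype=bool)
        within = S[mask].mean()
        between = S[off & ~mask].mean()
        assert within > between


class TestRandomForest:
    def test_separable_training_accuracy(self):
        emb, labels = _blob_embeddings()
        clf = train_random_forest(emb, labels, task="single", seed=0)
        preds = clf.predict_labels(emb.features)
        acc = np.mean([p[0] == l for p, l in zip(preds, labels)])
        assert acc >= 0.99

    def test_multilabel_constant_label(self):
        emb, _ = _blob_embeddings()
        labels = [["A"] for _ in emb.image_ids]
        clf = train_random_forest(emb, labels, task="multi", seed=0)
        assert all(p == ["A"] for p in clf.predict_labels(emb.features))

    def test_same_seed_same_predictions(self):
        emb, labels = _blob_embeddings(seed=3)
        a = train_random_forest(emb, labels, task="single", seed=1)
        b = train_random_forest(emb, labels, task="single", seed=1)
        assert np.array_equal(a.predict_scores(emb.features), b.predict_scores(emb.features))

    def test_empty_class_dropped_with_warning(self, caplog):
        emb, _ = _blob_embeddings()
        sets = [["A", "B"] if i == 0 else ["A"] for i in range(len(emb.image_ids))]
        sets[0] = ["A"]  # B never appears
        labels = [list(s) for s in sets]
        # emulate a vocabulary with an absent class via multilabel mode
        clf = train_random_forest(emb, labels, task="multi", seed=0)
        assert clf.classes == ["A"]


class TestMLP:
    def test_output_width_and_sanity_fit(self):
        emb, labels = _blob_embeddings(n_per_class=24, sep=5.0)
        params = {"max_epochs": 60, "hidden": (32, 16)}
        clf = train_mlp(emb, labels, task="single", mlp_params=params, seed=0)
        assert len(clf.classes) == 2
        scores = clf.predict_scores(emb.features)
        assert scores.shape == (len(emb.image_ids), 2)
        preds = clf.predict_labels(emb.features)
        acc = np.mean([p[0] == l for p, l in zip(preds, labels)])
        assert acc > 0.9

    def test_multilabel_sigmoid_scores_in_unit_interval(self):
        emb, labels = _blob_embeddings()
        sets = [[l] for l in labels]
        clf = train_mlp(emb, sets, task="multi", mlp_params={"max_epochs": 20, "hidden": (16, 8)}, seed=0)
        s = clf.predict_scores(emb.features)
        assert ((s >= 0) & (s <= 1)).all()

    def test_single_class_rejected(self):
        emb, _ = _blob_embeddings()
        with pytest.raises(ValueError, match="classes"):
            train_mlp(emb, [["A"]] * len(emb.image_ids), task="multi")

    def test_empty_validation_slice_rejected(self):
        emb, labels = _blob_embeddings(n_per_class=2)
        with pytest.raises(ValueError, match="validation"):
            train_mlp(emb, labels, task="single", mlp_params={"val_fraction": 0.01})


class TestCrossValidate:
    @pytest.fixture()
    def cv_setup(self):
        emb, labels = _blob_embeddings(n_per_class=20, n_classes=3, seed=5)
        ann = AnnotationTable(
            "custom", {c: [l] for c, l in zip(emb.compound_ids, labels)}
        )

        class _Rec:
            def __init__(self, c):
                self.compound_id = c

        plan = make_splits(ann, [_Rec(c) for c in emb.compound_ids], fold_count=5, seed=0)
        return emb, ann, plan

    def test_folds_partition_and_no_leakage(self, cv_setup):
        emb, ann, plan = cv_setup
        preds = cross_validate(emb, ann, plan, {"model": "rf", "task": "single", "seed": 0})
        assert len(preds) == 5
        test_compounds = [set(p.compound_ids) for p in preds]
        assert set().union(*test_compounds) == set(ann.annotated_compounds)
        for fold, p in enumerate(preds):
            train_c = set(plan.train_compounds(fold))
            assert not set(p.compound_ids) & train_c

    def test_rf_predictions_reproducible(self, cv_setup):
        emb, ann, plan = cv_setup
        a = cross_validate(emb, ann, plan, {"model": "rf", "task": "single", "seed": 2})
        b = cross_validate(emb, ann, plan, {"model": "rf", "task": "single", "seed": 2})
        for pa, pb in zip(a, b):
            assert pa.predicted == pb.predicted
            assert np.array_equal(pa.scores, pb.scores)

    def test_multilabel_mode_produces_label_sets(self, cv_setup):
        emb, ann, plan = cv_setup
        preds = cross_validate(emb, ann, plan, {"model": "rf", "task": "multi", "seed": 0})
        assert all(isinstance(p.predicted[0], list) for p in preds)


class TestPredictCompoundClasses:
    class _FixedClassifier:
        """Single-label stub cycling through a prescribed prediction list."""

        task = "single"

        def __init__(self, preds):
            self._preds = preds

        def predict_labels(self, X):
            return [[p] for p in self._preds[: len(X)]]

    def test_tally_and_order(self):
        preds = ["A"] * 30 + ["B"] * 4 + ["C"] * 2
        clf = self._FixedClassifier(preds)
        out = predict_compound_classes(clf, np.zeros((36, 4)), top_k=3)
        assert out == [("A", 30), ("B", 4), ("C", 2)]

    def test_unanimous_prediction(self):
        clf = self._FixedClassifier(["A"] * 7)
        assert predict_compound_classes(clf, np.zeros((7, 2))) == [("A", 7)]

    def test_count_tie_broken_lexically(self):
        clf = self._FixedClassifier(["B"] * 5 + ["A"] * 5)
        out = predict_compound_classes(clf, np.zeros((10, 2)), top_k=2)
        assert out == [("A", 5), ("B", 5)]

    def test_empty_replicates_rejected(self):
        clf = self._FixedClassifier([])
        with pytest.raises(ValueError):
            predict_compound_classes(clf, np.zeros((0, 2)))
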