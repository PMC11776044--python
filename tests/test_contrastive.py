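"""Multiview batches, contrastive losses, training loop, batchwise scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenocon.contrastive import (
    ContrastiveConfig,
    MultiviewBatch,
    batchwise_contrastive_loss,
    build_multiview_batch,
    self_supervised_loss,
    self_supervised_loss_grad,
    supervised_contrastive_loss,
    supervised_contrastive_loss_grad,
    train_semisupervised,
)
from phenocon.io_data import AnnotationTable
from phenocon.synthetic import generate_embedding_fixture

from oracles import brute_self_supervised_loss, brute_supervised_loss

TAU = 0.07


class TestMultiviewBatch:
    def test_structure_and_mutual_pairs(self, tiny_dataset):
        records, _, _ = tiny_dataset
        batch = build_multiview_batch(records, None, N=3, seed=0)
        assert len(batch.entries) == 6
        idx = np.arange(6)
        assert (batch.pair_index[batch.pair_index] == idx).all()
        assert (batch.pair_index != idx).all()

    def test_positive_is_same_compound(self, tiny_dataset):
        records, _, _ = tiny_dataset
        batch = build_multiview_batch(records, None, N=8, seed=1)
        for i in range(0, 16, 2):
            a, p = batch.entries[i], batch.entries[i + 1]
            assert records[a].compound_id == records[p].compound_id

    def test_single_image_compound_self_pairs(self):
        import copy

        from phenocon.io_data import ImageRecord

        rec = ImageRecord("only", "cX", "p", "w", 1, np.zeros((4, 4, 1)), ["a"])
        batch = build_multiview_batch([rec], None, N=1, seed=0)
        assert list(batch.entries) == [0, 0]

    def test_same_seed_identical_batches(self, tiny_dataset):
        records, _, _ = tiny_dataset
        a = build_multiview_batch(records, None, N=5, seed=9)
        b = build_multiview_batch(records, None, N=5, seed=9)
        assert np.array_equal(a.entries, b.entries)

    def test_invalid_n_rejected(self, tiny_dataset):
        records, _, _ = tiny_dataset
        with pytest.raises(ValueError):
            build_multiview_batch(records, None, N=0, seed=0)

    def test_mismatched_pair_labels_rejected(self):
        with pytest.raises(ValueError, match="label"):
            MultiviewBatch(
                entries=np.arange(4),
                pair_index=np.array([1, 0, 3, 2]),
                N=2,
                labels=np.array(["a", "b", "c", "c"]),
            )


class TestLossOracles:
    @pytest.mark.parametrize("trial", range(20))
    def test_self_loss_matches_double_loop(self, trial):
        rng = np.random.default_rng(trial)
        Z, pair, _ = generate_embedding_fixture(
            int(rng.integers(2, 7)), int(rng.integers(2, 9)), seed=1000 + trial
        )
        got = self_supervised_loss(Z, pair, TAU)
        want = brute_self_supervised_loss(Z, pair, TAU)
        assert got == pytest.approx(want, rel=1e-6)

    @pytest.mark.parametrize("trial", range(20))
    def test_supervised_loss_matches_triple_loop(self, trial):
        rng = np.random.default_rng(500 + trial)
        Z, pair, labels = generate_embedding_fixture(
            int(rng.integers(2, 7)), int(rng.integers(2, 9)),
            {"n_classes": 3}, seed=2000 + trial,
        )
        got = supervised_contrastive_loss(Z, pair, labels, TAU)
        want = brute_supervised_loss(Z, pair, labels, TAU)
        assert got == pytest.approx(want, rel=1e-6)

    def test_n1_has_zero_loss(self):
        Z, pair, _ = generate_embedding_fixture(1, 4, seed=0)
        assert self_supervised_loss(Z, pair, TAU) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_pairs", [2, 3, 5])
    def test_identical_embeddings_give_log_2n_minus_1(self, n_pairs):
        Z, pair, _ = generate_embedding_fixture(n_pairs, 4, {"identical_rows": True}, seed=1)
        want = np.log(2 * n_pairs - 1)
        assert self_supervised_loss(Z, pair, TAU) == pytest.approx(want, rel=1e-9)

    def test_identical_embeddings_same_label_supervised(self):
        Z, pair, _ = generate_embedding_fixture(2, 4, {"identical_rows": True}, seed=2)
        labels = np.array(["L", "L", "L", "L"])
        got = supervised_contrastive_loss(Z, pair, labels, TAU)
        assert got == pytest.approx(np.log(3), rel=1e-9)

    @pytest.mark.parametrize("trial", range(25))
    def test_supervised_reduces_to_self_when_labels_distinct(self, trial):
        rng = np.random.default_rng(trial)
        Z, pair, labels = generate_embedding_fixture(
            int(rng.integers(2, 7)), int(rng.integers(2, 9)),
            {"distinct_labels": True}, seed=3000 + trial,
        )
        sup = supervised_contrastive_loss(Z, pair, labels, TAU)
        slf = self_supervised_loss(Z, pair, TAU)
        assert sup == pytest.approx(slf, rel=1e-9)

    def test_permutation_invariance(self):
        Z, pair, labels = generate_embedding_fixture(5, 6, {"n_classes": 2}, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(Z))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(Z))
        Zp, pairp, labp = Z[perm], inv[pair[perm]], labels[perm]
        assert self_supervised_loss(Zp, pairp, TAU) == pytest.approx(
            self_supervised_loss(Z, pair, TAU), abs=1e-9
        )
        assert supervised_contrastive_loss(Zp, pairp, labp, TAU) == pytest.approx(
            supervised_contrastive_loss(Z, pair, labels, TAU), abs=1e-9
        )

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        n_pairs=st.integers(2, 6),
        dim=st.integers(2, 8),
        n_classes=st.integers(1, 4),
        seed=st.integers(0, 10_000),
        tau=st.floats(0.05, 2.0),
    )
    def test_losses_are_nonnegative(self, n_pairs, dim, n_classes, seed, tau):
        Z, pair, labels = generate_embedding_fixture(
            n_pairs, dim, {"n_classes": n_classes}, seed=seed
        )
        assert self_supervised_loss(Z, pair, tau) >= 0
        assert supervised_contrastive_loss(Z, pair, labels, tau) >= 0

    def test_non_normalized_rows_rejected(self):
        Z, pair, _ = generate_embedding_fixture(2, 4, seed=0)
        with pytest.raises(ValueError, match="unit"):
            self_supervised_loss(2.0 * Z, pair, TAU)

    def test_nan_rejected(self):
        Z, pair, _ = generate_embedding_fixture(2, 4, seed=0)
        Z = Z.copy()
        Z[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            self_supervised_loss(Z, pair, TAU)

    def test_supervised_requires_labels_everywhere(self):
        Z, pair, _ = generate_embedding_fixture(2, 4, seed=0)
        labels = np.array(["a", "a", None, None], dtype=object)
        with pytest.raises(ValueError, match="label"):
            supervised_contrastive_loss(Z, pair, labels, TAU)


class TestLossGradients:
    @pytest.mark.parametrize("supervised", [False, True])
    def test_analytic_gradient_matches_finite_differences(self, supervised):
        rng = np.random.default_rng(11)
        Z, pair, labels = generate_embedding_fixture(3, 5, {"n_classes": 2}, seed=11)
        tau = 0.2
        if supervised:
            loss, dZ = supervised_contrastive_loss_grad(Z, pair, labels, tau)
            f = lambda W: brute_supervised_loss(W, pair, labels, tau)
        else:
            loss, dZ = self_supervised_loss_grad(Z, pair, tau)
            f = lambda W: brute_self_supervised_loss(W, pair, tau)
        eps = 1e-6
        for _ in range(6):
            D = rng.normal(size=Z.shape)
            fd = (f(Z + eps * D) - f(Z - eps * D)) / (2 * eps)
            an = float((dZ * D).sum())
            assert an == pytest.approx(fd, rel=1e-4)


class TestTraining:
    def test_history_has_one_row_per_epoch(self, tiny_model):
        _, history = tiny_model
        assert len(history) == 4
        assert list(history.columns) == ["epoch", "self_loss", "sup_loss"]

    def test_unannotated_run_matches_pure_self_supervised(self, tiny_preprocessed):
        records, _, _ = tiny_preprocessed
        config = ContrastiveConfig(
            projector_dim=8, feature_dim=16, batch_size=8, max_epochs=2, seed=5
        )
        empty = AnnotationTable("custom", {})
        m1, h1 = train_semisupervised(records, empty, config)
        m2, h2 = train_semisupervised(records, empty, config)
        for w1, w2 in zip(m1.net.get_weights(), m2.net.get_weights()):
            assert np.array_equal(w1, w2)
        assert h1["self_loss"].tolist() == h2["self_loss"].tolist()
        assert h1["sup_loss"].isna().all()

    def test_projection_is_unit_norm_and_deterministic(self, tiny_model, tiny_preprocessed):
        model, _ = tiny_model
        records, _, _ = tiny_preprocessed
        Z1 = model.project(records[:6])
        Z2 = model.project(records[:6])
        assert Z1.shape == (6, model.config.projector_dim)
        np.testing.assert_allclose(np.linalg.norm(Z1, axis=1), 1.0, atol=1e-5)
        assert np.array_equal(Z1, Z2)

    def test_duplicate_images_embed_identically(self, tiny_model, tiny_preprocessed):
        model, _ = tiny_model
        records, _, _ = tiny_preprocessed
        Z = model.project([records[0], records[0]])
        assert np.array_equal(Z[0], Z[1])

    def test_training_reduces_self_loss(self, tiny_preprocessed):
        records, annotations, _ = tiny_preprocessed
        wins = 0
        for seed in (1, 2, 3):
            config = ContrastiveConfig(
                projector_dim=16, feature_dim=32, batch_size=16, max_epochs=6, seed=seed
            )
            _, history = train_semisupervised(records, annotations, config)
            wins += int(history["self_loss"].iloc[-1] < history["self_loss"].iloc[0])
        assert wins >= 2

    def test_model_save_load_round_trip(self, tiny_model, tiny_preprocessed, tmp_path):
        from phenocon.contrastive import EncoderModel

        model, _ = tiny_model
        records, _, _ = tiny_preprocessed
        model.save(tmp_path / "ckpt")
        back = EncoderModel.load(tmp_path / "ckpt")
        assert back.trained
        assert np.array_equal(back.project(records[:4]), model.project(records[:4]))


class TestBatchwiseLoss:
    def test_consistent_compound_scores_lowest(self, tiny_model):
        """A compound whose replicate latents coincide, batched against
        mutually spread compounds, must get the lowest aggregated score."""
        model, _ = tiny_model
        from phenocon.io_data import ImageRecord

        # construct latents directly through a stub model facade
        rng = np.random.default_rng(0)
        dim = 64  # high dim: independent random unit vectors are near-orthogonal
        Zs = []
        recs = []
        base0 = rng.normal(size=dim)
        for c in range(6):
            for j in range(3):
                v = base0 if c == 0 else rng.normal(size=dim)
                Zs.append(v / np.linalg.norm(v))
                recs.append(
                    ImageRecord(f"c{c}_r{j}", f"c{c}", "p", f"w{c}", j + 1,
                                np.zeros((4, 4, 1)), ["a"])
                )

        class StubModel:
            trained = True
            config = model.config

            def project(self, records):
                return np.array([Zs[recs.index(r)] for r in records])

        _, comp = batchwise_contrastive_loss(StubModel(), recs, batch_size=18, seed=0)
        assert comp.iloc[0]["compound_id"] == "c0"

    def test_identical_geometry_breaks_ties_lexically(self, tiny_model):
        model, _ = tiny_model
        from phenocon.io_data import ImageRecord

        v = np.zeros(4)
        v[0] = 1.0
        recs = [
            ImageRecord(f"{c}_r{j}", c, "p", f"w{c}", j + 1, np.zeros((2, 2, 1)), ["a"])
            for c in ["b", "a", "c"]
            for j in range(2)
        ]

        class StubModel:
            trained = True
            config = model.config

            def project(self, records):
                return np.tile(v, (len(records), 1))

        _, comp = batchwise_contrastive_loss(StubModel(), recs, batch_size=6, seed=0)
        assert comp["score"].nunique() == 1
        assert comp["compound_id"].tolist() == ["a", "b", "c"]

    def test_min_aggregate_never_exceeds_mean(self, tiny_model, tiny_preprocessed):
        model, _ = tiny_model
        records, _, _ = tiny_preprocessed
        _, comp_min = batchwise_contrastive_loss(model, records, 16, seed=0, aggregate="min")
        _, comp_mean = batchwise_contrastive_loss(model, records, 16, seed=0, aggregate="mean")
        merged = comp_min.merge(comp_mean, on="compound_id", suffixes=("_min", "_mean"))
        assert (merged["score_min"] <= merged["score_mean"] + 1e-12).all()

    def test_untrained_model_rejected(self, tiny_preprocessed):
        from phenocon.contrastive import EncoderModel

        records, _, _ = tiny_preprocessed
        cfg = ContrastiveConfig(projector_dim=8, feature_dim=16)
        fresh = EncoderModel(cfg, 3, (32, 32))
        with pytest.raises(ValueError, match="trained"):
            batchwise_contrastive_loss(fresh, records, 8, seed=0)

    def test_deterministic_given_seed(self, tiny_model, tiny_preprocessed):
        model, _ = tiny_model
        records, _, _ = tiny_preprocessed
        a = batchwise_contrastive_loss(model, records, 16, seed=3)[1]
        b = batchwise_contrastive_loss(model, records, 16, seed=3)[1]
        assert a.equals(b)
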