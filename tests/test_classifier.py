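import numpy as np
import pytest

from ubisite import classifier as clf
from ubisite import embedding as emb
from ubisite import synthetic
from ubisite.seq_data import FragmentDataset, ProteinRecord


@pytest.fixture(scope="module")
def small_embedding():
    vocab = emb.build_vocab(2)
    return emb.random_embedding(vocab, dim=20, sigma=0.01, seed=5)


@pytest.fixture(scope="module")
def separable_dataset():
    """Strong planted motif: easy for descent sanity checks."""
    return synthetic.gen_labeled_fragments(
        150, 150, synthetic.plant_motif(8.0), seed=3
    )


def quick_config(**kw):
    defaults = dict(epochs=3, batch_size=64, seed=0)
    defaults.update(kw)
    return clf.TrainConfig(**defaults)


class TestBuildModel:
    def test_embedding_transferred_verbatim(self, small_embedding):
        model = clf.build_model(clf.CNNConfig(), small_embedding, seed=0)
        np.testing.assert_array_equal(
            model.params["E"], small_embedding.matrix.astype(np.float32)
        )

    def test_valid_padding_length_chain(self):
        lengths = clf.layer_lengths(clf.CNNConfig(), 30)
        assert lengths == [30, 28, 14, 12, 6, 4, 2]

    def test_flattened_width(self, small_embedding):
        model = clf.build_model(clf.CNNConfig(), small_embedding)
        assert model.params["Wd0"].shape[0] == 2 * 128  # 256

    def test_parameter_count_matches_closed_form(self, small_embedding):
        cfg = clf.CNNConfig()
        model = clf.build_model(cfg, small_embedding)
        expected = clf.expected_parameter_count(
            cfg, small_embedding.vocab.size, small_embedding.dim
        )
        assert model.parameter_count() == expected

    def test_forward_scores_strictly_inside_unit_interval(
        self, small_embedding, rng
    ):
        model = clf.build_model(clf.CNNConfig(), small_embedding, seed=1)
        tokens = rng.integers(0, 401, size=(16, 30)).astype(np.int32)
        scores = clf._forward(model, tokens)
        assert np.all((scores > 0.0) & (scores < 1.0))

    def test_vocab_embedding_shape_mismatch_rejected(self, small_embedding):
        bad = emb.EmbeddingMatrix(
            small_embedding.matrix[:100], small_embedding.vocab, {}
        )
        with pytest.raises(ValueError, match="vocabulary"):
            clf.build_model(clf.CNNConfig(), bad)


class TestBCELoss:
    def test_perfect_prediction_is_near_zero(self):
        assert clf.bce_loss([1, 0], [1 - 1e-9, 1e-9]) < 1e-6

    def test_uniform_scores_give_ln_two(self):
        assert clf.bce_loss([1, 0, 1], [0.5, 0.5, 0.5]) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_clipping_keeps_loss_finite(self):
        loss = clf.bce_loss([1], [0.0])
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-7))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            clf.bce_loss([1, 0], [0.5])


class TestTraining:
    def test_loss_decreases_on_separable_data(self, separable_dataset):
        vocab = emb.build_vocab(2)
        model = clf.build_model(
            clf.CNNConfig(), emb.random_embedding(vocab, 20, seed=1), seed=0
        )
        clf.train(model, separable_dataset, quick_config(epochs=12))
        assert model.history[-1] < model.history[0]
        assert np.isfinite(model.history).all()

    def test_freezing_keeps_embedding_bit_identical(
        self, small_embedding, separable_dataset
    ):
        model = clf.build_model(clf.CNNConfig(), small_embedding, seed=0)
        before = model.params["E"].copy()
        clf.train(model, separable_dataset, quick_config(freeze_embedding=True))
        np.testing.assert_array_equal(model.params["E"], before)

    def test_fine_tuning_updates_embedding(self, small_embedding, separable_dataset):
        model = clf.build_model(clf.CNNConfig(), small_embedding, seed=0)
        before = model.params["E"].copy()
        clf.train(model, separable_dataset, quick_config())
        assert not np.array_equal(model.params["E"], before)

    def test_identical_seeds_identical_runs(self, separable_dataset):
        vocab = emb.build_vocab(2)
        losses = []
        for _ in range(2):
            model = clf.build_model(
                clf.CNNConfig(), emb.random_embedding(vocab, 20, seed=4), seed=2
            )
            clf.train(model, separable_dataset, quick_config(seed=11))
            losses.append(model.history)
        assert losses[0] == losses[1]

    def test_empty_or_single_class_rejected(self, small_embedding):
        model = clf.build_model(clf.CNNConfig(), small_embedding)
        with pytest.raises(ValueError, match="empty"):
            clf.train(model, FragmentDataset([]), quick_config())
        one_class = synthetic.gen_labeled_fragments(
            5, 5, synthetic.null_motif(), seed=0
        )
        one_class.fragments = [
            f for f in one_class.fragments if f.label == "positive"
        ]
        with pytest.raises(ValueError, match="both classes"):
            clf.train(model, one_class, quick_config())


@pytest.fixture(scope="module")
def trained(separable_dataset):
    vocab = emb.build_vocab(2)
    model = clf.build_model(
        clf.CNNConfig(), emb.random_embedding(vocab, 20, seed=1), seed=0
    )
    clf.train(model, separable_dataset, quick_config(epochs=10))
    return model


class TestPrediction:
    def test_order_preserved_under_permutation(self, trained, separable_dataset):
        frags = separable_dataset.fragments[:20]
        scores = clf.predict_fragments(trained, frags)
        perm = list(reversed(range(20)))
        permuted = clf.predict_fragments(trained, [frags[i] for i in perm])
        np.testing.assert_allclose(permuted, scores[perm])

    def test_duplicate_fragment_scores_identically(self, trained, separable_dataset):
        f = separable_dataset.fragments[0]
        scores = clf.predict_fragments(trained, [f, f])
        assert scores[0] == scores[1]

    def test_batch_size_invariance(self, trained, separable_dataset):
        frags = separable_dataset.fragments[:30]
        full = clf.predict_fragments(trained, frags, batch_size=30)
        tiny = clf.predict_fragments(trained, frags, batch_size=1)
        np.testing.assert_allclose(full, tiny, rtol=1e-6)

    def test_wrong_fragment_length_rejected(self, trained):
        bad = synthetic.gen_labeled_fragments(
            1, 1, synthetic.null_motif(), seed=0, window=21
        ).fragments
        with pytest.raises(ValueError, match="length"):
            clf.predict_fragments(trained, bad)

    def test_protein_without_lysine_yields_nothing(self, trained):
        assert clf.predict_protein(trained, ProteinRecord("p", "ACDEF" * 10)) == []

    def test_every_lysine_scored(self, trained, rng):
        seq = "".join(rng.choice(list("ACDK"), size=120))
        preds = clf.predict_protein(trained, ProteinRecord("p", seq))
        assert len(preds) == seq.count("K")
        assert all(seq[p.position - 1] == "K" for p in preds)

    def test_threshold_one_flags_nothing(self, trained, rng):
        seq = "".join(rng.choice(list("ACDK"), size=120))
        preds = clf.predict_protein(trained, ProteinRecord("p", seq), threshold=1.0)
        assert not any(p.predicted for p in preds)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, separable_dataset):
        vocab = emb.build_vocab(2)
        model = clf.build_model(
            clf.CNNConfig(), emb.random_embedding(vocab, 20, seed=1), seed=0
        )
        clf.train(model, separable_dataset, quick_config())
        clf.save_model(model, tmp_path / "model")
        back = clf.load_model(tmp_path / "model")
        frags = separable_dataset.fragments[:10]
        np.testing.assert_array_equal(
            clf.predict_fragments(model, frags), clf.predict_fragments(back, frags)
        )
        assert back.history == model.history
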