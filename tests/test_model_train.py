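"""Reference classifier: initialization, loss, gradients, training loop, prediction."""

import math

import numpy as np
import pytest

from curribatch.batching import build_batchsets, build_schedule
from curribatch.model_train import (
    ModelSpec,
    TrainConfig,
    _pad_batch,
    bce_loss,
    init_params,
    loss_and_grads,
    predict,
    train,
)
from curribatch.preprocess import build_vocabulary, encode
from curribatch.synth_corpus import SynthConfig, generate_corpus

TINY = ModelSpec(vocab_size=12, n_labels=3, embedding_dim=3,
                 filter_widths=(2, 3), n_filters=2)


class TestInit:
    def test_seeded_determinism_and_seed_sensitivity(self):
        a, b, c = init_params(TINY, 0), init_params(TINY, 0), init_params(TINY, 1)
        assert all(np.array_equal(a[k], b[k]) for k in a)
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_parameter_count_closed_form(self):
        # hand count: emb 12·3=36; conv2 2·3·2+2=14; conv3 3·3·2+2=20;
        # out 4·3+3=15 → total 85
        assert TINY.n_parameters == 85
        params = init_params(TINY, 0)
        assert sum(v.size for v in params.values()) == 85


class TestBCELoss:
    def test_closed_forms(self):
        assert bce_loss(np.array([[0.0]]), np.array([[1.0]])) == pytest.approx(
            math.log(2)
        )
        assert bce_loss(np.array([[20.0]]), np.array([[1.0]])) < 1e-8

    def test_two_by_two_hand_arithmetic(self):
        # elements: (0,y=1)→ln2; (2,y=0)→ln(1+e²)... computed by scalar math
        x = np.array([[0.0, 2.0], [-1.0, 3.0]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = (
            math.log(2)
            + math.log(1 + math.exp(2))
            + math.log(1 + math.exp(-1))
            + math.log(1 + math.exp(-3))
        ) / 4
        assert bce_loss(x, y) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        params = init_params(TINY, 3)
        docs = [rng.integers(0, 12, size=n) for n in (5, 7)]
        ids, lengths = _pad_batch(docs, min_len=3)
        targets = rng.integers(0, 2, size=(2, 3)).astype(float)
        _, grads = loss_and_grads(params, TINY, ids, lengths, targets)
        eps = 1e-6
        for name in params:
            flat_idx = [0, params[name].size // 2, params[name].size - 1]
            for fi in set(flat_idx):
                orig = params[name].flat[fi]
                params[name].flat[fi] = orig + eps
                lp, _ = loss_and_grads(params, TINY, ids, lengths, targets)
                params[name].flat[fi] = orig - eps
                lm, _ = loss_and_grads(params, TINY, ids, lengths, targets)
                params[name].flat[fi] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[name].flat[fi] == pytest.approx(fd, abs=1e-7), name


def _tiny_training_setup(seed=0):
    corpus = generate_corpus(
        SynthConfig(
            n_examples=60, n_labels=5, vocab_size=60, doc_length_range=(8, 14),
            mean_labels_per_example=1.5, max_labels_per_example=3,
            signal_strength=0.9, seed=seed,
        )
    )
    vocab = build_vocabulary(corpus, 1000)
    enc = encode(corpus, vocab)
    bsets = build_batchsets(corpus, 12, seed)
    spec = ModelSpec(vocab_size=vocab.n_ids, n_labels=5,
                     embedding_dim=8, n_filters=4)
    return enc, bsets, spec


class TestTrain:
    def test_zero_epochs_returns_initialization(self):
        enc, bsets, spec = _tiny_training_setup()
        cfg = TrainConfig(batch_size=12, seed=1)
        st = train(enc, bsets, spec, cfg, n_epochs=0)
        init = init_params(spec, 1)
        assert st.loss_history == []
        assert all(np.array_equal(st.params[k], init[k]) for k in init)

    def test_loss_decreases_on_learnable_corpus(self):
        enc, bsets, spec = _tiny_training_setup()
        cfg = TrainConfig(
            batch_size=12, schedule=build_schedule([("sdd", 8)]), seed=2
        )
        st = train(enc, bsets, spec, cfg)
        assert st.loss_history[-1] < st.loss_history[0]
        assert all(np.isfinite(st.loss_history))

    def test_deterministic_loss_history(self):
        enc, bsets, spec = _tiny_training_setup()
        cfg = TrainConfig(batch_size=12, schedule=build_schedule([("udd", 2), ("idd", 2)]), seed=3)
        a = train(enc, bsets, spec, cfg)
        b = train(enc, bsets, spec, cfg)
        assert a.loss_history == b.loss_history

    def test_missing_batchset_kind_rejected(self):
        enc, bsets, spec = _tiny_training_setup()
        del bsets[list(bsets)[0]]
        cfg = TrainConfig(batch_size=12, seed=0)
        with pytest.raises(ValueError):
            train(enc, bsets, spec, cfg)

    def test_validation_tracks_best_epoch(self):
        enc, bsets, spec = _tiny_training_setup()
        cfg = TrainConfig(batch_size=12, schedule=build_schedule([("sdd", 4)]), seed=4)
        st = train(enc, bsets, spec, cfg, val_encoded=enc)
        assert st.best_epoch is not None
        assert len(st.val_f1_history) == 4


class TestPredict:
    def test_all_zero_parameters_score_half_and_threshold_is_inclusive(self):
        enc, _, spec = _tiny_training_setup()
        params = {k: np.zeros_like(v) for k, v in init_params(spec, 0).items()}
        pm = predict(params, enc, threshold=0.5, model_spec=spec)
        assert np.allclose(pm.scores, 0.5)
        assert pm.decisions.all()  # score 0.5 at threshold 0.5 → positive

    def test_threshold_monotonicity(self):
        enc, bsets, spec = _tiny_training_setup()
        params = init_params(spec, 5)
        lo = predict(params, enc, threshold=0.3, model_spec=spec)
        hi = predict(params, enc, threshold=0.7, model_spec=spec)
        assert hi.decisions.sum() <= lo.decisions.sum()

    def test_label_dimension_mismatch_rejected(self):
        enc, _, _ = _tiny_training_setup()
        wrong = ModelSpec(vocab_size=61, n_labels=4, embedding_dim=8, n_filters=4)
        with pytest.raises(ValueError):
            predict(init_params(wrong, 0), enc, model_spec=wrong)
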