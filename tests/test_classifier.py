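"""Classifier: gradients, splits, reproducibility, inference invariances."""

from __future__ import annotations

import numpy as np
import pytest

from vqrefine import _transformer as T
from vqrefine.classifier import (
    ClassifierResults,
    ModelConfig,
    SentenceClassifier,
    SplitSpec,
    VocabularyMismatchError,
    decide,
    grid_search,
    make_split,
    train,
)
from vqrefine.encoding import Sentence, build_vocabulary
from vqrefine.vcf_io import FAIL, PASS
from conftest import DESK_ENCODING


class TestModelConfigValidation:
    def test_heads_must_divide_hidden(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(hidden_size=64, num_heads=6)

    def test_published_range_configs_accepted(self):
        # full-scale settings are expressible even though not the default
        cfg = ModelConfig(hidden_size=768, num_layers=12, num_heads=12,
                          learning_rate=5e-5, batch_size=1300, epochs=21)
        assert cfg.epochs == 21

    @pytest.mark.parametrize("kwargs", [
        dict(learning_rate=0.0), dict(batch_size=0), dict(epochs=-1),
        dict(hidden_size=0, num_heads=1),
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestMakeSplit:
    def _corpus(self, n):
        return [Sentence(f"T{i}", PASS if i % 2 else FAIL) for i in range(n)]

    def test_sixty_forty(self):
        train_set, val_set = make_split(self._corpus(10), SplitSpec(seed=0))
        assert len(train_set) == 6 and len(val_set) == 4
        texts = {s.text for s in train_set} | {s.text for s in val_set}
        assert len(texts) == 10  # disjoint and exhaustive

    def test_subsample_cap(self):
        train_set, val_set = make_split(
            self._corpus(10), SplitSpec(subsample_size=5, seed=0)
        )
        assert len(train_set) + len(val_set) == 5

    def test_reproducible(self):
        a = make_split(self._corpus(20), SplitSpec(seed=3))
        b = make_split(self._corpus(20), SplitSpec(seed=3))
        assert [s.text for s in a[0]] == [s.text for s in b[0]]

    def test_too_small_corpus(self):
        with pytest.raises(ValueError):
            make_split(self._corpus(1), SplitSpec())

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences everywhere."""
        rng = np.random.default_rng(0)
        V, L, layers, heads = 11, 6, 2, 2
        params = T.init_params(V, L, hidden=8, layers=layers, heads=heads,
                               ff=16, seed=1)
        ids = rng.integers(0, V, size=(3, L))
        mask = np.ones((3, L), dtype=np.int64)
        mask[0, 4:] = 0
        labels = np.array([0, 1, 1])
        _, grads = T.loss_and_grads(params, ids, mask, labels, layers, heads)
        eps = 1e-6
        for key, p in params.items():
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = T.loss_and_grads(params, ids, mask, labels, layers, heads)
                flat[i] = orig - eps
                lm, _ = T.loss_and_grads(params, ids, mask, labels, layers, heads)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[i] == pytest.approx(numeric, abs=5e-9), key

    def test_padding_positions_do_not_affect_logits(self):
        params = T.init_params(7, 8, hidden=8, layers=1, heads=2, ff=16, seed=0)
        ids = np.array([[2, 4, 5, 0, 0, 0, 0, 0]])
        mask = np.array([[1, 1, 1, 0, 0, 0, 0, 0]])
        base = T.forward(params, ids, mask, 1, 2)
        ids2 = ids.copy()
        ids2[0, 3:] = 6  # garbage under the mask
        assert np.allclose(T.forward(params, ids2, mask, 1, 2), base)


def _planted_corpus(n, seed, flip=0.0):
    """Labels follow a threshold on one token family: Q=hi -> PASS."""
    rng = np.random.default_rng(seed)
    corpus = []
    for i in range(n):
        hi = rng.random() < 0.5
        noise_tok = f"N={rng.integers(0, 5)}"
        label = PASS if hi else FAIL
        if flip and rng.random() < flip:
            label = FAIL if label == PASS else PASS
        corpus.append(Sentence(f"Q={'hi' if hi else 'lo'} {noise_tok}", label))
    return corpus


class TestTraining:
    def test_smoke_one_epoch(self):
        corpus = _planted_corpus(20, seed=0)
        vocab = build_vocabulary(corpus)
        cfg = ModelConfig(hidden_size=32, num_layers=2, num_heads=2,
                          feedforward_size=64, epochs=1, max_sequence_length=16,
                          seed=0)
        results = train(corpus[:16], corpus[16:], vocab, cfg, DESK_ENCODING)
        assert len(results.training_log) == 1
        assert "train_loss" in results.training_log[0]

    def test_reproducible_training_log(self):
        corpus = _planted_corpus(60, seed=1)
        vocab = build_vocabulary(corpus)
        cfg = ModelConfig(hidden_size=16, num_layers=1, num_heads=2,
                          feedforward_size=32, epochs=2, max_sequence_length=16,
                          seed=5)
        a = train(corpus[:40], corpus[40:], vocab, cfg, DESK_ENCODING)
        b = train(corpus[:40], corpus[40:], vocab, cfg, DESK_ENCODING)
        assert a.training_log == b.training_log

    def test_learns_planted_threshold_rule(self, tiny_fit):
        results, _, _, _ = tiny_fit
        assert results.training_log[-1]["val_accuracy"] >= 0.95

    def test_summary_mentions_architecture(self, tiny_fit):
        results, _, _, _ = tiny_fit
        text = results.summary()
        assert "AdamW" in text and "val AUC" in text
        assert f"{results.n_params:,}" in text


class TestPredictProba:
    def test_probabilities_valid_and_order_preserving(self, tiny_fit):
        results, vocab, _, val_set = tiny_fit
        probs = results.predict_proba(val_set, vocab)
        assert probs.shape == (len(val_set),)
        assert np.all((probs >= 0) & (probs <= 1))
        again = results.predict_proba(val_set, vocab)
        assert np.array_equal(probs, again)

    def test_batching_invariance(self, tiny_fit):
        results, vocab, _, val_set = tiny_fit
        big = results.predict_proba(val_set, vocab, batch_size=10_000)
        small = results.predict_proba(val_set, vocab, batch_size=7)
        assert np.allclose(big, small, rtol=1e-9, atol=1e-12)

    def test_duplicate_sentences_identical_probabilities(self, tiny_fit):
        results, vocab, _, val_set = tiny_fit
        doubled = [val_set[0], val_set[0]]
        probs = results.predict_proba(doubled, vocab)
        assert probs[0] == probs[1]

    def test_untrained_model_still_valid(self):
        corpus = _planted_corpus(10, seed=2)
        vocab = build_vocabulary(corpus)
        cfg = ModelConfig(hidden_size=16, num_layers=1, num_heads=2,
                          feedforward_size=32, epochs=0, max_sequence_length=16)
        results = train(corpus[:8], corpus[8:], vocab, cfg, DESK_ENCODING)
        probs = results.predict_proba(corpus, vocab)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_vocab_fingerprint_mismatch_fails_fast(self, tiny_fit):
        results, _, _, val_set = tiny_fit
        wrong = build_vocabulary([Sentence("A B C")])
        with pytest.raises(VocabularyMismatchError):
            results.predict_proba(val_set, wrong)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_fit, tmp_path):
        results, vocab, _, val_set = tiny_fit
        path = tmp_path / "model.ckpt.npz"
        results.save(path)
        loaded = ClassifierResults.load(path, vocab=vocab)
        assert loaded.config == results.config
        assert loaded.training_log == results.training_log
        assert np.array_equal(
            loaded.predict_proba(val_set, vocab),
            results.predict_proba(val_set, vocab),
        )

    def test_load_refuses_wrong_vocab(self, tiny_fit, tmp_path):
        results, _, _, _ = tiny_fit
        path = tmp_path / "model.ckpt.npz"
        results.save(path)
        with pytest.raises(VocabularyMismatchError):
            ClassifierResults.load(path, vocab=build_vocabulary([Sentence("Z")]))


class TestGridSearch:
    def test_single_candidate_returned(self):
        corpus = _planted_corpus(30, seed=3)
        vocab = build_vocabulary(corpus)
        cfg = ModelConfig(hidden_size=16, num_layers=1, num_heads=2,
                          feedforward_size=32, epochs=1, max_sequence_length=16)
        best, board = grid_search(corpus[:20], corpus[20:], vocab, [cfg],
                                  DESK_ENCODING, seed=0)
        from dataclasses import replace

        assert best == replace(cfg, seed=0)
        assert len(board) == 1

    def test_trained_beats_untrained_on_planted_rule(self):
        corpus = _planted_corpus(200, seed=4)
        vocab = build_vocabulary(corpus)
        base = dict(hidden_size=32, num_layers=1, num_heads=2,
                    feedforward_size=64, max_sequence_length=16)
        random_cfg = ModelConfig(epochs=0, **base)
        trained_cfg = ModelConfig(epochs=4, **base)
        best, board = grid_search(
            corpus[:140], corpus[140:], vocab, [random_cfg, trained_cfg],
            DESK_ENCODING, seed=0,
        )
        assert best.epochs == 4
        assert len(board) == 2

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], [], build_vocabulary([Sentence("A")]), [])


class TestDecide:
    @pytest.mark.parametrize("p,threshold,expected", [
        (0.5, 0.5, PASS), (0.49, 0.5, FAIL), (1.0, 0.5, PASS), (0.0, 0.0, PASS),
    ])
    def test_boundary_convention(self, p, threshold, expected):
        assert decide(p, threshold) == expected

    def test_threshold_sweep_monotone(self):
        rng = np.random.default_rng(0)
        probs = rng.random(50)
        previous_pass = None
        for threshold in np.linspace(0, 1, 11):
            passing = {i for i, p in enumerate(probs) if decide(p, threshold) == PASS}
            if previous_pass is not None:
                assert passing <= previous_pass  # raising threshold only removes
            previous_pass = passing

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            decide(1.5)
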