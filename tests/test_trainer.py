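"""Losses, analytic gradients and the SGD training loop."""

import math

import numpy as np
import pytest

from pkword2vec.corpus import NON_MEDICAL, Vocabulary, negative_table
from pkword2vec.prior import PriorSource
from pkword2vec.trainer import (
    EmbeddingPair,
    TrainConfig,
    TrainingExample,
    _apply_micro,
    gamma,
    gradients,
    pk_step_loss,
    psi,
    sgns_pair_loss,
    total_loss,
    train,
)


def _vocab(counts):
    words = [f"w{i}" for i in range(len(counts))]
    return Vocabulary(words, np.array(counts), [NON_MEDICAL] * len(counts),
                      int(sum(counts)))


def _scalar_total_loss(batch, pair, vocab, config):
    """Independent scalar re-evaluation of the objective, term by term."""
    sigma = lambda x: 1.0 / (1.0 + math.exp(-x))
    total = 0.0
    for ex in batch:
        for c, ctx in enumerate(ex.contexts):
            v = pair.center[ex.center]
            total += -math.log(sigma(float(pair.context[ctx] @ v)))
            for k in np.atleast_2d(ex.negatives)[c]:
                total += -math.log(sigma(-float(pair.context[k] @ v)))
        if ex.prior is not None:
            def cos(a, b):
                return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
            g = config.tau / (vocab.counts[ex.center] / vocab.total_tokens)
            val = 1.0 - cos(pair.center[ex.center], pair.center[ex.prior])
            if config.context_regularization:
                val += 1.0 - cos(pair.context[ex.center],
                                 pair.context[ex.prior])
            total += config.alpha * g * val
    return total


def _random_batch(rng, n_words, dim, n_examples=4, K=3, with_prior=True):
    vocab = _vocab(rng.integers(1, 20, size=n_words))
    pair = EmbeddingPair(rng.standard_normal((n_words, dim)),
                         rng.standard_normal((n_words, dim)))
    batch = []
    for _ in range(n_examples):
        center = int(rng.integers(n_words))
        n_ctx = int(rng.integers(1, 4))
        contexts = tuple(int(rng.integers(n_words)) for _ in range(n_ctx))
        negs = rng.integers(0, n_words, size=(n_ctx, K))
        prior = int(rng.integers(n_words)) if with_prior and rng.random() < 0.7 else None
        if prior == center:
            prior = (prior + 1) % n_words
        batch.append(TrainingExample(center, contexts, negs, prior))
    return vocab, pair, batch


class TestLossTerms:
    def test_sgns_loss_at_zero(self):
        z = np.zeros(4)
        # sigma(0) = 0.5 for both the positive and the single negative term
        assert sgns_pair_loss(z, z, z[None, :]) == pytest.approx(
            -2 * math.log(0.5))

    def test_sgns_loss_limit(self):
        u = np.array([100.0, 0.0])
        v = np.array([100.0, 0.0])
        neg = np.array([[-100.0, 0.0]])
        assert sgns_pair_loss(u, v, neg) == pytest.approx(0.0, abs=1e-9)

    def test_sgns_loss_random_against_scalar_oracle(self, rng):
        u, v = rng.standard_normal(5), rng.standard_normal(5)
        negs = rng.standard_normal((4, 5))
        sigma = lambda x: 1 / (1 + math.exp(-x))
        expected = -math.log(sigma(float(u @ v))) - sum(
            math.log(sigma(-float(n @ v))) for n in negs)
        assert sgns_pair_loss(u, v, negs) == pytest.approx(expected, rel=1e-12)

    def test_gamma(self):
        vocab = _vocab([10, 90])  # rel_freq 0.1 and 0.9
        assert gamma(0, vocab, tau=0.1) == pytest.approx(1.0)
        assert gamma(0, vocab, tau=1e-5) == pytest.approx(1e-4)
        # halving the relative frequency doubles gamma
        assert gamma(0, vocab, 1e-3) == pytest.approx(
            2 * gamma(0, _vocab([20, 80]), 1e-3))

    def test_psi_bounds_and_composition(self, rng):
        a = rng.standard_normal(4)
        assert psi(a, a, a, a) == pytest.approx(0.0)
        assert psi(a, -a, a, -a) == pytest.approx(4.0)
        u_t, u_j, v_t, v_j = (rng.standard_normal(4) for _ in range(4))
        from pkword2vec.vectors import cosine
        assert psi(u_t, u_j, v_t, v_j) == pytest.approx(
            2 - cosine(u_t, u_j) - cosine(v_t, v_j))
        assert psi(u_t, u_j, v_t, v_j, context_regularization=False) == \
            pytest.approx(1 - cosine(v_t, v_j))
        with pytest.raises(ValueError):
            psi(np.zeros(4), u_j, v_t, v_j)

    def test_pk_step_loss(self, rng):
        vocab = _vocab([5, 5])
        pair = EmbeddingPair(rng.standard_normal((2, 4)),
                             rng.standard_normal((2, 4)))
        config = TrainConfig(dim=4)
        assert pk_step_loss(0, None, pair, vocab, config) == 0.0
        same = EmbeddingPair(np.ones((2, 4)), np.ones((2, 4)))
        assert pk_step_loss(0, 1, same, vocab, config) == pytest.approx(0.0)
        expected = gamma(0, vocab, config.tau) * psi(
            pair.context[0], pair.context[1], pair.center[0], pair.center[1])
        assert pk_step_loss(0, 1, pair, vocab, config) == pytest.approx(expected)


class TestTotalLossAndGradients:
    def test_alpha_zero_is_pure_sgns(self, rng):
        vocab, pair, batch = _random_batch(rng, 8, 5)
        config = TrainConfig(dim=5, alpha=0.0)
        expected = sum(
            sgns_pair_loss(pair.context[ctx], pair.center[ex.center],
                           pair.context[np.atleast_2d(ex.negatives)[c]])
            for ex in batch for c, ctx in enumerate(ex.contexts))
        assert total_loss(batch, pair, vocab, config) == pytest.approx(
            expected, rel=1e-12)

    def test_total_loss_against_scalar_oracle(self, rng):
        vocab, pair, batch = _random_batch(rng, 10, 6)
        for alpha in (0.0, 0.5):
            config = TrainConfig(dim=6, alpha=alpha, tau=1e-2)
            assert total_loss(batch, pair, vocab, config) == pytest.approx(
                _scalar_total_loss(batch, pair, vocab, config), rel=1e-10)

    def test_identical_rows_zero_pk(self, rng):
        vocab = _vocab([3, 3, 3])
        row = rng.standard_normal(4)
        pair = EmbeddingPair(np.tile(row, (3, 1)), np.tile(row, (3, 1)))
        batch = [TrainingExample(0, (1,), np.array([[2]]), prior=1)]
        c0 = TrainConfig(dim=4, alpha=0.0, negatives=1)
        c1 = TrainConfig(dim=4, alpha=5.0, negatives=1)
        assert total_loss(batch, pair, vocab, c1) == pytest.approx(
            total_loss(batch, pair, vocab, c0))

    def test_sgns_gradient_closed_form(self, rng):
        vocab = _vocab([2, 2, 2])
        pair = EmbeddingPair(rng.standard_normal((3, 4)),
                             rng.standard_normal((3, 4)))
        batch = [TrainingExample(0, (1,), np.array([[2]]), prior=None)]
        config = TrainConfig(dim=4, alpha=0.0, negatives=1)
        gc, gx = gradients(batch, pair, vocab, config)
        sig = lambda x: 1 / (1 + np.exp(-x))
        u, v, n = pair.context[1], pair.center[0], pair.context[2]
        assert np.allclose(gc[0], (sig(u @ v) - 1) * u + sig(n @ v) * n)
        assert np.allclose(gx[1], (sig(u @ v) - 1) * v)
        assert np.allclose(gx[2], sig(n @ v) * v)

    @pytest.mark.parametrize("alpha,ctx_reg", [(0.0, True), (0.7, True),
                                               (0.7, False)])
    def test_central_difference_oracle(self, rng, alpha, ctx_reg):
        vocab, pair, batch = _random_batch(rng, 9, 6)
        config = TrainConfig(dim=6, alpha=alpha, tau=1e-2,
                             context_regularization=ctx_reg)
        gc, gx = gradients(batch, pair, vocab, config)
        h = 1e-6
        for matrix, grad in ((pair.center, gc), (pair.context, gx)):
            touched = np.flatnonzero(np.abs(grad).sum(axis=1))
            for i in touched[:4]:
                for d in range(config.dim):
                    orig = matrix[i, d]
                    matrix[i, d] = orig + h
                    up = total_loss(batch, pair, vocab, config)
                    matrix[i, d] = orig - h
                    dn = total_loss(batch, pair, vocab, config)
                    matrix[i, d] = orig
                    numeric = (up - dn) / (2 * h)
                    assert grad[i, d] == pytest.approx(
                        numeric, rel=1e-5, abs=1e-7)

    def test_aligned_context_vectors_zero_cosine_gradient(self):
        vocab = _vocab([4, 4])
        u = np.array([1.0, 2.0, 0.5])
        pair = EmbeddingPair(
            np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            np.array([u, 2 * u]))  # parallel context rows: cos = 1, max
        batch = [TrainingExample(0, (), np.zeros((0, 1), dtype=int), prior=1)]
        config = TrainConfig(dim=3, alpha=1.0, tau=1.0, negatives=1)
        _gc, gx = gradients(batch, pair, vocab, config)
        assert np.allclose(gx, 0.0, atol=1e-12)

    def test_micro_step_equals_gradient_step(self, rng):
        # the in-place training update must equal params -= lr * gradients
        vocab, pair, batch = _random_batch(rng, 8, 5)
        config = TrainConfig(dim=5, alpha=0.3, tau=1e-2)
        gc, gx = gradients(batch, pair, vocab, config)
        from pkword2vec.trainer import _batch_arrays
        pc, px, ng, pt, pj, pw = _batch_arrays(batch, vocab, config)
        stepped = pair.copy()
        lr = 0.01
        _apply_micro(stepped.center, stepped.context, lr, pc, px, ng,
                     pt, pj, pw, config.context_regularization)
        assert np.allclose(stepped.center, pair.center - lr * gc, atol=1e-12)
        assert np.allclose(stepped.context, pair.context - lr * gx, atol=1e-12)


class TestTraining:
    def test_determinism(self, small_world):
        config = TrainConfig(dim=8, epochs=2, seed=11, alpha=1.0)
        docs, vocab = small_world["corpus"].docs, small_world["vocab"]
        a, _ = train(docs, vocab, small_world["sources"], config)
        b, _ = train(docs, vocab, small_world["sources"], config)
        assert np.array_equal(a.center, b.center)
        assert np.array_equal(a.context, b.context)

    def test_alpha_zero_equals_sgns_path(self, small_world):
        config = TrainConfig(dim=8, epochs=2, seed=3, alpha=0.0)
        docs, vocab = small_world["corpus"].docs, small_world["vocab"]
        with_priors, _ = train(docs, vocab, small_world["sources"], config)
        without, _ = train(docs, vocab, (), config)
        assert np.array_equal(with_priors.center, without.center)
        assert np.array_equal(with_priors.context, without.context)

    def test_loss_decreases_on_repeated_sentence(self):
        docs = [["the", "cat", "sat", "on", "the", "mat"]] * 40
        vocab = Vocabulary(["the", "cat", "sat", "on", "mat"],
                           np.array([80, 40, 40, 40, 40]),
                           [NON_MEDICAL] * 5, 240)
        config = TrainConfig(dim=8, epochs=10, seed=5, window=2, negatives=2)
        _pair, trace = train(docs, vocab, (), config)
        per_pair = [t["loss_sgns"] for t in trace]
        assert per_pair[-1] < per_pair[0]

    def test_trace_contents(self, small_world):
        config = TrainConfig(dim=8, epochs=2, seed=1, alpha=2.0)
        pair, trace = train(small_world["corpus"].docs, small_world["vocab"],
                            small_world["sources"], config)
        assert len(trace) == 2
        assert all(t["loss_sgns"] > 0 for t in trace)
        assert all(t["loss_pk_weighted"] > 0 for t in trace)
        assert np.isfinite(pair.center).all()

    def test_regularization_pull_monotone_in_alpha(self):
        # toy corpus, one prior pair (t, j): stronger alpha pulls
        # cos(v_t, v_j) monotonically upward (same seeds at every alpha)
        from pkword2vec.corpus import build_vocabulary

        rng = np.random.default_rng(0)
        words = [f"w{i}" for i in range(10)]
        docs = [[words[i] for i in rng.integers(0, 10, size=12)]
                for _ in range(25)]
        vocab = build_vocabulary(docs)
        t, j = vocab.index["w0"], vocab.index["w1"]
        source = PriorSource(
            name="pair", category=NON_MEDICAL, theta=0.9,
            candidates={t: (np.array([j]), np.array([0.95]), np.array([1.0]))})
        means = []
        for alpha in (0.0, 1e-3, 1.0):
            vals = []
            for seed in range(5):
                config = TrainConfig(dim=8, epochs=10, seed=seed, alpha=alpha,
                                     window=2, negatives=2)
                pair, _ = train(docs, vocab, [source], config)
                v0, v1 = pair.center[t], pair.center[j]
                vals.append(float(v0 @ v1 /
                                  (np.linalg.norm(v0) * np.linalg.norm(v1))))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_empty_corpus_rejected(self, small_world):
        with pytest.raises(ValueError):
            train([["zzz-not-in-vocab"]], small_world["vocab"], (),
                  TrainConfig(dim=4, epochs=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(window=0)
        with pytest.raises(ValueError):
            TrainConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(tau=0.0)
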