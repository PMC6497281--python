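import math

import numpy as np
import pytest

from medtagger.corpus import Corpus, build_vocabulary
from medtagger.network import (
    BiLSTMLayer,
    LSTMDirection,
    ModelConfig,
    TaggerModel,
    bidirectional_layer,
    encode_characters,
    make_batches,
    recurrent_step,
    softmax,
)
from medtagger.synthetic import GeneratorConfig, generate_domain_pair
from medtagger.training import TrainConfig, train_variant


def make_direction(d_in, d_hidden, seed=0, dtype=np.float64):
    return LSTMDirection(d_in, d_hidden, np.random.default_rng(seed), np.dtype(dtype))


def zero_direction(d_in, d_hidden):
    d = make_direction(d_in, d_hidden)
    d.Wx[...] = 0.0
    d.Wh[...] = 0.0
    d.b[...] = 0.0
    return d


class TestRecurrentStep:
    def test_zero_parameters_give_zero_state(self):
        d = zero_direction(3, 2)
        x = np.array([[1.0, -2.0, 0.5]])
        h, c = recurrent_step(x, np.zeros((1, 2)), np.zeros((1, 2)), d)
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_matches_hand_computed_gates(self):
        """2-unit cell with hand-set weights against an independently
        written gate computation."""
        d = zero_direction(1, 2)
        d.Wx[...] = np.array([[0.5, -0.3, 0.2, 0.8, -0.1, 0.4, 0.7, -0.6]])
        d.Wh[...] = np.arange(16).reshape(2, 8) * 0.05
        d.b[...] = np.array([0.1, -0.2, 0.3, 0.0, 0.05, -0.05, 0.2, 0.1])
        x = np.array([[0.9]])
        h_prev = np.array([[0.2, -0.4]])
        c_prev = np.array([[0.1, 0.3]])

        def sig(v):
            return 1.0 / (1.0 + math.exp(-v))

        a = (x @ d.Wx + h_prev @ d.Wh + d.b)[0]
        i = [sig(a[0]), sig(a[1])]
        f = [sig(a[2]), sig(a[3])]
        o = [sig(a[4]), sig(a[5])]
        g = [math.tanh(a[6]), math.tanh(a[7])]
        c_exp = [f[k] * c_prev[0, k] + i[k] * g[k] for k in range(2)]
        h_exp = [o[k] * math.tanh(c_exp[k]) for k in range(2)]

        h, c = recurrent_step(x, h_prev, c_prev, d)
        np.testing.assert_allclose(h[0], h_exp, rtol=1e-12)
        np.testing.assert_allclose(c[0], c_exp, rtol=1e-12)

    def test_deterministic(self):
        d = make_direction(3, 4, seed=5)
        x = np.ones((2, 3))
        h0 = np.zeros((2, 4))
        out1 = recurrent_step(x, h0, h0, d)
        out2 = recurrent_step(x, h0, h0, d)
        np.testing.assert_array_equal(out1[0], out2[0])


class TestBidirectionalLayer:
    def make_layer(self, d_in=3, d_h=4, seed=0, mode="sum"):
        return BiLSTMLayer(d_in, d_h, np.random.default_rng(seed), np.dtype(np.float64), mode)

    def test_length_one_equals_sum_of_single_steps(self):
        layer = self.make_layer()
        x = np.random.default_rng(1).normal(size=(1, 3))
        out = bidirectional_layer(x, layer)
        hf, _ = recurrent_step(x, np.zeros((1, 4)), np.zeros((1, 4)), layer.fwd)
        hb, _ = recurrent_step(x, np.zeros((1, 4)), np.zeros((1, 4)), layer.bwd)
        np.testing.assert_allclose(out, hf + hb, rtol=1e-12)

    def test_palindromic_input_with_tied_directions(self):
        layer = self.make_layer()
        layer.bwd.Wx[...] = layer.fwd.Wx
        layer.bwd.Wh[...] = layer.fwd.Wh
        layer.bwd.b[...] = layer.fwd.b
        half = np.random.default_rng(2).normal(size=(3, 3))
        x = np.concatenate([half, half[::-1]], axis=0)  # palindrome
        out = bidirectional_layer(x, layer)
        np.testing.assert_allclose(out, out[::-1], rtol=1e-10)

    def test_reversing_input_and_swapping_directions_reverses_output(self):
        layer = self.make_layer(seed=3)
        swapped = self.make_layer(seed=3)
        swapped.fwd, swapped.bwd = layer.bwd, layer.fwd
        x = np.random.default_rng(4).normal(size=(5, 3))
        out = bidirectional_layer(x, layer)
        out_rev = bidirectional_layer(x[::-1], swapped)
        np.testing.assert_allclose(out_rev, out[::-1], rtol=1e-12)

    def test_order_sensitivity(self):
        """Additive direction combination still depends on token order."""
        layer = self.make_layer(seed=6)
        x = np.random.default_rng(7).normal(size=(6, 3))
        shuffled = x[[3, 1, 5, 0, 4, 2]]
        out = bidirectional_layer(x, layer)
        out_shuf = bidirectional_layer(shuffled, layer)
        assert np.abs(out.sum(axis=0) - out_shuf.sum(axis=0)).max() > 1e-6

    def test_empty_sequence_rejected(self):
        layer = self.make_layer()
        with pytest.raises(ValueError):
            bidirectional_layer(np.zeros((0, 3)), layer)


class TestCharacterEncoder:
    def make_encoder(self, d_emb=2, d_h=3, n_chars=10, seed=0):
        rng = np.random.default_rng(seed)
        layer = BiLSTMLayer(d_emb, d_h, rng, np.dtype(np.float64), mode="final_concat")
        emb = rng.normal(size=(n_chars, d_emb))
        return emb, layer

    def test_single_character_word(self):
        emb, layer = self.make_encoder()
        vec = encode_characters([4], emb, layer)
        x = emb[[4]]
        hf, _ = recurrent_step(x, np.zeros((1, 3)), np.zeros((1, 3)), layer.fwd)
        hb, _ = recurrent_step(x, np.zeros((1, 3)), np.zeros((1, 3)), layer.bwd)
        np.testing.assert_allclose(vec, np.concatenate([hf[0], hb[0]]), rtol=1e-12)

    def test_deterministic(self):
        emb, layer = self.make_encoder()
        v1 = encode_characters([1, 2, 3], emb, layer)
        v2 = encode_characters([1, 2, 3], emb, layer)
        np.testing.assert_array_equal(v1, v2)

    def test_one_char_difference_changes_vector(self):
        emb, layer = self.make_encoder(seed=8)
        v1 = encode_characters([1, 2, 3], emb, layer)
        v2 = encode_characters([1, 5, 3], emb, layer)
        assert np.abs(v1 - v2).max() > 1e-8

    def test_empty_word_rejected(self):
        emb, layer = self.make_encoder()
        with pytest.raises(ValueError):
            encode_characters([], emb, layer)


class TestForwardPass:
    @pytest.fixture
    def model_and_batch(self, tiny_target, tiny_vocab, tiny_model_config):
        model = TaggerModel(tiny_vocab, tiny_model_config, seed=2)
        batch = make_batches(tiny_target, tiny_vocab, 8, tiny_model_config.np_dtype)[0]
        return model, batch

    def test_distributions_sum_to_one(self, model_and_batch):
        model, batch = model_and_batch
        for task in ("pos", "ner"):
            probs = model.forward_pass(batch, task)
            sums = probs.sum(axis=-1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_inference_deterministic(self, model_and_batch):
        model, batch = model_and_batch
        p1 = model.forward_pass(batch, "ner", training=False)
        p2 = model.forward_pass(batch, "ner", training=False)
        np.testing.assert_array_equal(p1, p2)

    def test_ner_head_emits_eleven_labels(self, model_and_batch):
        model, batch = model_and_batch
        assert model.forward_pass(batch, "ner").shape[-1] == 11

    def test_unknown_task_rejected(self, model_and_batch):
        model, batch = model_and_batch
        with pytest.raises(ValueError, match="task"):
            model.forward_pass(batch, "chunking")

    def test_dropout_requires_rng_and_perturbs(self, model_and_batch, tiny_vocab, tiny_target):
        cfg = ModelConfig(
            word_embedding_dim=3, char_embedding_dim=2, char_hidden=2,
            layer_hidden=2, dropout_rate=0.5, dtype="float64",
        )
        model = TaggerModel(tiny_vocab, cfg, seed=2)
        batch = make_batches(tiny_target, tiny_vocab, 8, cfg.np_dtype)[0]
        with pytest.raises(ValueError):
            model.forward_pass(batch, "ner", training=True)
        rng = np.random.default_rng(0)
        p_train = model.forward_pass(batch, "ner", training=True, rng=rng)
        p_eval = model.forward_pass(batch, "ner", training=False)
        assert np.abs(p_train - p_eval).max() > 1e-9


def expected_param_count(cfg: ModelConfig, n_words, n_chars, n_pos, n_ner,
                         trunk_depth=2, task_layers=True, tasks=("pos", "ner")):
    """Closed-form parameter count for the architecture."""

    def bilstm(d_in, d_h):
        return 2 * (d_in * 4 * d_h + d_h * 4 * d_h + 4 * d_h)

    d_repr = cfg.word_embedding_dim + 2 * cfg.char_hidden
    total = n_words * cfg.word_embedding_dim + n_chars * cfg.char_embedding_dim
    total += bilstm(cfg.char_embedding_dim, cfg.char_hidden)
    d_in = d_repr
    for _ in range(trunk_depth):
        total += bilstm(d_in, cfg.layer_hidden)
        d_in = cfg.layer_hidden
    for task in tasks:
        n_labels = n_pos if task == "pos" else n_ner
        if task_layers:
            total += bilstm(d_in, cfg.layer_hidden)
            total += cfg.layer_hidden * n_labels + n_labels
        else:
            total += d_in * n_labels + n_labels
    return total


class TestParameterCount:
    def test_default_architecture_recurrent_stack_is_pinned(self, tiny_vocab):
        model = TaggerModel(tiny_vocab, ModelConfig(), seed=0)
        # char layer + transferred + shared + two task layers at the
        # reference sizes (150/300 cells, 100/50-dim embeddings)
        stack = sum(
            v.size
            for k, v in model.parameters().items()
            if k.split(".")[0] in ("char", "transferred", "shared")
            or ".layer." in k
        )
        assert stack == 6_250_800

    def test_closed_form_matches_model(self, tiny_vocab, tiny_model_config):
        model = TaggerModel(tiny_vocab, tiny_model_config, seed=0)
        expected = expected_param_count(
            tiny_model_config,
            tiny_vocab.n_words,
            tiny_vocab.n_chars,
            tiny_vocab.n_pos,
            tiny_vocab.n_ner,
        )
        assert model.param_count() == expected


class TestGradientsAndLearning:
    def test_analytic_gradients_match_finite_differences(self, tiny_model_config):
        """Central-difference check of every parameter block on a 2-unit,
        3-token instance."""
        cfg = GeneratorConfig(seed=13, n_sentences_general=0, n_sentences_target=4)
        _, corpus = generate_domain_pair(cfg)
        corpus = Corpus(
            [s for s in corpus.sentences][:1], "grad"
        )
        vocab = build_vocabulary([corpus])
        model = TaggerModel(vocab, tiny_model_config, seed=9)
        batch = make_batches(corpus, vocab, 1, tiny_model_config.np_dtype)[0]
        for task in ("ner", "pos"):
            _, grads = model.loss_and_grads(batch, task)
            params = model.parameters()
            eps = 1e-6
            rng = np.random.default_rng(17)
            for name, arr in params.items():
                flat = arr.ravel()
                n_probe = min(8, flat.size)
                for i in rng.choice(flat.size, size=n_probe, replace=False):
                    old = flat[i]
                    flat[i] = old + eps
                    lp = model.loss(batch, task)
                    flat[i] = old - eps
                    lm = model.loss(batch, task)
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    ana = grads[name].ravel()[i] if name in grads else 0.0
                    denom = max(abs(num) + abs(ana), 1e-4)
                    assert abs(num - ana) / denom < 1e-4, (task, name, num, ana)

    def test_loss_decreases_monotonically_without_dropout(self):
        cfg = GeneratorConfig(seed=21, n_sentences_general=0, n_sentences_target=10)
        _, corpus = generate_domain_pair(cfg)
        mc = ModelConfig(
            word_embedding_dim=8, char_embedding_dim=4, char_hidden=4,
            layer_hidden=8, dropout_rate=0.0, dtype="float64",
        )
        res = train_variant(
            "BRNN", None, corpus,
            TrainConfig(epochs=5, minibatch_size=10, seed=21, variant="BRNN"),
            model_config=mc,
        )
        losses = [r.losses["ner"] for r in res.log.records]
        assert all(b < a for a, b in zip(losses, losses[1:]))


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tmp_path, tiny_vocab, tiny_model_config):
        model = TaggerModel(tiny_vocab, tiny_model_config, seed=4)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TaggerModel.load(path)
        for name, arr in model.parameters().items():
            np.testing.assert_array_equal(loaded.parameters()[name], arr)
        assert loaded.vocab.fingerprint() == tiny_vocab.fingerprint()

    def test_softmax_rows_normalised(self):
        z = np.random.default_rng(0).normal(size=(3, 5)) * 10
        np.testing.assert_allclose(softmax(z).sum(axis=-1), 1.0, atol=1e-12)
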