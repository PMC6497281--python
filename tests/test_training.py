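import numpy as np
import pytest

from medtagger.experiments import split_corpus
from medtagger.network import TaggerModel, make_batches
from medtagger.synthetic import GeneratorConfig, generate_domain_pair
from medtagger.training import (
    TrainConfig,
    TransferPackage,
    extract_transfer_package,
    initialize_transferred_layer,
    train_general,
    train_multitask,
    train_variant,
)
from medtagger.corpus import build_vocabulary
from medtagger.network import bidirectional_layer


@pytest.fixture(scope="module")
def pair():
    cfg = GeneratorConfig(seed=31, n_sentences_general=50, n_sentences_target=30)
    return generate_domain_pair(cfg)


@pytest.fixture(scope="module")
def fast_cfg():
    from medtagger.network import ModelConfig

    return ModelConfig(
        word_embedding_dim=6,
        char_embedding_dim=4,
        char_hidden=3,
        layer_hidden=5,
        dropout_rate=0.5,
        dtype="float64",
    )


class TestTrainConfig:
    def test_lr_schedule(self):
        cfg = TrainConfig(learning_rate=0.01, lr_decay=0.9, epochs=3)
        assert cfg.lr_at_epoch(0) == 0.01
        assert cfg.lr_at_epoch(2) == pytest.approx(0.0081)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_bad_variant_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(variant="CRF")


class TestTrainGeneral:
    def test_loss_decreases(self, pair, fast_cfg):
        general, _ = pair
        model, package = train_general(
            general, TrainConfig(epochs=3, minibatch_size=10, seed=1), fast_cfg
        )
        # compare a fresh model's loss with the trained one on the data
        vocab = model.vocab
        batches = make_batches(general, vocab, 10, fast_cfg.np_dtype)
        fresh = TaggerModel(vocab, fast_cfg, seed=1, tasks=("ner",), trunk_depth=1, task_layers=False)
        initial = float(np.mean([fresh.loss(b, "ner") for b in batches]))
        final = float(np.mean([model.loss(b, "ner") for b in batches]))
        assert final < initial

    def test_same_seed_bit_identical_package(self, pair, fast_cfg):
        general, _ = pair
        cfg = TrainConfig(epochs=2, minibatch_size=10, seed=7)
        _, p1 = train_general(general, cfg, fast_cfg)
        _, p2 = train_general(general, cfg, fast_cfg)
        for name in ("U_fwd", "W_fwd", "b_fwd", "U_bwd", "W_bwd", "b_bwd", "word_emb"):
            np.testing.assert_array_equal(getattr(p1, name), getattr(p2, name))

    def test_package_round_trip(self, tmp_path, pair, fast_cfg):
        general, _ = pair
        _, package = train_general(
            general, TrainConfig(epochs=1, minibatch_size=10, seed=2), fast_cfg
        )
        path = tmp_path / "pkg.npz"
        package.save(path)
        loaded = TransferPackage.load(path)
        np.testing.assert_array_equal(loaded.U_fwd, package.U_fwd)
        assert loaded.source_fingerprint == package.source_fingerprint
        assert loaded.words == package.words


class TestTransferInitialization:
    def make_package_and_model(self, pair, fast_cfg, epochs=1):
        general, target = pair
        phase1, package = train_general(
            general, TrainConfig(epochs=epochs, minibatch_size=10, seed=3), fast_cfg
        )
        vocab = build_vocabulary([target])
        model = TaggerModel(vocab, fast_cfg, seed=99)
        return phase1, package, model

    def test_uw_blocks_assigned_exactly(self, pair, fast_cfg):
        _, package, model = self.make_package_and_model(pair, fast_cfg)
        initialize_transferred_layer(model, package)
        layer = model.transferred_layer
        np.testing.assert_array_equal(layer.fwd.Wx, package.U_fwd)
        np.testing.assert_array_equal(layer.fwd.Wh, package.W_fwd)
        np.testing.assert_array_equal(layer.bwd.Wx, package.U_bwd)
        np.testing.assert_array_equal(layer.bwd.Wh, package.W_bwd)

    def test_biases_not_transferred_by_default(self, pair, fast_cfg):
        _, package, model = self.make_package_and_model(pair, fast_cfg)
        before = model.transferred_layer.fwd.b.copy()
        initialize_transferred_layer(model, package)
        np.testing.assert_array_equal(model.transferred_layer.fwd.b, before)

    def test_other_blocks_unchanged(self, pair, fast_cfg):
        _, package, model = self.make_package_and_model(pair, fast_cfg)
        snapshot = {
            k: v.copy()
            for k, v in model.parameters().items()
            if not k.startswith("transferred.")
        }
        initialize_transferred_layer(model, package)
        for k, v in snapshot.items():
            np.testing.assert_array_equal(model.parameters()[k], v)

    def test_shape_mismatch_names_block(self, pair, fast_cfg):
        from medtagger.network import ModelConfig

        _, package, _ = self.make_package_and_model(pair, fast_cfg)
        bigger = ModelConfig(
            word_embedding_dim=6, char_embedding_dim=4, char_hidden=3,
            layer_hidden=9, dropout_rate=0.5, dtype="float64",
        )
        _, target = pair
        model = TaggerModel(build_vocabulary([target]), bigger, seed=0)
        with pytest.raises(ValueError, match="U_fwd"):
            initialize_transferred_layer(model, package)

    def test_transferred_layer_reproduces_phase1_outputs_with_biases(
        self, pair, fast_cfg, rng
    ):
        phase1, package, model = self.make_package_and_model(pair, fast_cfg)
        initialize_transferred_layer(model, package, transfer_biases=True)
        d = fast_cfg.word_repr_dim
        for _ in range(5):
            x = rng.normal(size=(int(rng.integers(1, 9)), d))
            out_phase1 = bidirectional_layer(x, phase1.transferred_layer)
            out_model = bidirectional_layer(x, model.transferred_layer)
            np.testing.assert_array_equal(out_model, out_phase1)


class TestMultitaskTraining:
    def test_alternation_fairness(self, pair, fast_cfg, monkeypatch):
        """POS and NER minibatch update counts differ by at most one per
        epoch (here: strictly equal)."""
        _, target = pair
        vocab = build_vocabulary([target])
        model = TaggerModel(vocab, fast_cfg, seed=5)
        counts = {"pos": 0, "ner": 0}
        original = TaggerModel.loss_and_grads

        def counting(self, batch, task, **kw):
            counts[task] += 1
            return original(self, batch, task, **kw)

        monkeypatch.setattr(TaggerModel, "loss_and_grads", counting)
        train_multitask(model, target, TrainConfig(epochs=2, minibatch_size=8, seed=5))
        assert counts["pos"] == counts["ner"] > 0

    def test_log_has_one_record_per_epoch(self, pair, fast_cfg):
        _, target = pair
        vocab = build_vocabulary([target])
        model = TaggerModel(vocab, fast_cfg, seed=6)
        _, log = train_multitask(
            model, target, TrainConfig(epochs=3, minibatch_size=8, seed=6)
        )
        assert [r.epoch for r in log.records] == [0, 1, 2]
        assert all(set(r.losses) == {"pos", "ner"} for r in log.records)

    def test_ner_loss_decreases_over_training(self, pair, fast_cfg):
        _, target = pair
        vocab = build_vocabulary([target])
        model = TaggerModel(vocab, fast_cfg, seed=8)
        _, log = train_multitask(
            model, target, TrainConfig(epochs=10, minibatch_size=8, seed=8)
        )
        assert log.records[-1].losses["ner"] < log.records[0].losses["ner"]


class TestVariants:
    def test_brnn_warns_and_ignores_general(self, pair, fast_cfg):
        general, target = pair
        with pytest.warns(UserWarning, match="ignor"):
            res = train_variant(
                "BRNN", general, target,
                TrainConfig(epochs=1, minibatch_size=10, seed=1, variant="BRNN"),
                model_config=fast_cfg,
            )
        assert res.model.tasks == ("ner",)

    def test_transfer_variant_requires_general_or_package(self, pair, fast_cfg):
        _, target = pair
        with pytest.raises(ValueError, match="TMBRNN"):
            train_variant(
                "TMBRNN", None, target,
                TrainConfig(epochs=1, minibatch_size=10, seed=1),
                model_config=fast_cfg,
            )

    def test_tmbrnn_composition_and_tasks(self, pair, fast_cfg):
        general, target = pair
        res = train_variant(
            "TMBRNN", general, target,
            TrainConfig(epochs=1, minibatch_size=10, seed=2),
            model_config=fast_cfg,
            general_config=TrainConfig(epochs=1, minibatch_size=10, seed=2),
        )
        assert res.model.tasks == ("pos", "ner")
        assert res.package is not None

    def test_all_variants_emit_comparable_reports(self, pair, fast_cfg):
        general, target = pair
        train, test = split_corpus(target)
        cfg = TrainConfig(epochs=1, minibatch_size=10, seed=3)
        _, package = train_general(general, cfg, fast_cfg)
        reports = {}
        for variant in ("BRNN", "TBRNN", "MBRNN", "TMBRNN"):
            res = train_variant(
                variant, None, train,
                TrainConfig(epochs=1, minibatch_size=10, seed=3, variant=variant),
                model_config=fast_cfg,
                package=package if variant in ("TBRNN", "TMBRNN") else None,
                eval_corpus=test,
            )
            reports[variant] = res.report
        assert all(0 <= r.micro_f <= 100 for r in reports.values())

    def test_same_seed_reproduces_final_metrics(self, pair, fast_cfg):
        _, target = pair
        train, test = split_corpus(target)
        cfg = TrainConfig(epochs=2, minibatch_size=10, seed=11, variant="BRNN")
        r1 = train_variant("BRNN", None, train, cfg, model_config=fast_cfg, eval_corpus=test)
        r2 = train_variant("BRNN", None, train, cfg, model_config=fast_cfg, eval_corpus=test)
        assert r1.report.as_dict() == r2.report.as_dict()


def test_extract_package_copies_arrays(pair, fast_cfg):
    general, _ = pair
    model, package = train_general(
        general, TrainConfig(epochs=1, minibatch_size=10, seed=4), fast_cfg
    )
    package.U_fwd[...] = 0.0
    assert np.abs(model.transferred_layer.fwd.Wx).sum() > 0
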