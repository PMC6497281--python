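"""Model/Results surface over the training pipeline.

:class:`TransferMultitaskTagger` is constructed from corpora plus
configuration; :meth:`fit` runs the selected variant of the two-phase
procedure and returns a :class:`TaggerResults` carrying the trained
network, the per-epoch training log and (optionally) an evaluation
report, with a ``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path

from medtagger.corpus import Corpus, Sentence, Token, read_conll
from medtagger.metrics import MetricsReport, evaluate_corpora, render_report, round_half_up
from medtagger.network import ModelConfig, TaggerModel
from medtagger.training import (
    VARIANTS,
    TrainConfig,
    TrainingLog,
    TransferPackage,
    train_variant,
)


class TransferMultitaskTagger:
    """A transfer + multitask bidirectional LSTM tagger to be fitted.

    Parameters
    ----------
    target : Corpus
        The small in-domain training corpus (POS + BIO NER columns).
    general : Corpus, optional
        The large general-domain corpus used for Phase-1 pre-training;
        required by the transfer variants unless ``package`` is given.
    variant : str
        One of BRNN, TBRNN, MBRNN, TMBRNN (the default — the full model).
    model_config, train_config
        Architecture sizes and optimisation settings; defaults are the
        full-scale reference configuration.
    package : TransferPackage, optional
        Pre-trained Phase-1 weights; skips Phase-1 training.

    Examples
    --------
    >>> tagger = TransferMultitaskTagger(target, general, variant="TMBRNN")
    >>> res = tagger.fit(eval_corpus=test)
    >>> print(res.summary())
    """

    def __init__(
        self,
        target: Corpus,
        general: Corpus | None = None,
        variant: str = "TMBRNN",
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        package: TransferPackage | None = None,
        general_config: TrainConfig | None = None,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if len(target) == 0:
            raise ValueError("target corpus is empty")
        self.target = target
        self.general = general
        self.variant = variant
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig(variant=variant)
        self.package = package
        self.general_config = general_config

    @classmethod
    def from_files(
        cls,
        target_path: str | Path,
        general_path: str | Path | None = None,
        **kwargs,
    ) -> "TransferMultitaskTagger":
        target = read_conll(target_path)
        general = read_conll(general_path) if general_path else None
        return cls(target, general, **kwargs)

    def fit(self, eval_corpus: Corpus | None = None) -> "TaggerResults":
        result = train_variant(
            self.variant,
            self.general,
            self.target,
            self.train_config,
            model_config=self.model_config,
            package=self.package,
            general_config=self.general_config,
            eval_corpus=eval_corpus,
        )
        return TaggerResults(self, result.model, result.log, result.report, result.package)


class TaggerResults:
    """Fit results: the trained network, training log and scores."""

    def __init__(
        self,
        spec: TransferMultitaskTagger,
        network: TaggerModel,
        log: TrainingLog,
        report: MetricsReport | None = None,
        package: TransferPackage | None = None,
    ):
        self.model_spec = spec
        self.network = network
        self.log = log
        self.report = report
        self.package = package

    @property
    def variant(self) -> str:
        return self.model_spec.variant

    def predict(self, corpus: Corpus) -> Corpus:
        """Corpus with NER columns replaced by the model's predictions."""
        tags = self.network.predict_tags(corpus)
        sentences = [
            Sentence(
                tuple(
                    Token(t.surface, t.pos, tag)
                    for t, tag in zip(sent.tokens, sent_tags)
                )
            )
            for sent, sent_tags in zip(corpus.sentences, tags)
        ]
        return Corpus(sentences, domain_name=corpus.domain_name + "+pred")

    def evaluate(self, gold: Corpus) -> MetricsReport:
        """Score the model's predictions on ``gold`` (also stored on
        ``self.report``)."""
        self.report = evaluate_corpora(gold, self.predict(gold))
        return self.report

    def save(self, path: str | Path) -> None:
        self.network.save(path)

    def summary(self) -> str:
        cfg = self.model_spec.train_config
        lines = [
            "Transfer + multitask bidirectional LSTM tagger",
            "=" * 54,
            f"{'variant':<24}{self.variant}",
            f"{'tasks':<24}{', '.join(self.network.tasks)}",
            f"{'epochs trained':<24}{len(self.log)}",
            f"{'learning rate (final)':<24}"
            f"{self.log.records[-1].learning_rate if self.log.records else cfg.learning_rate:.6f}",
            f"{'minibatch size':<24}{cfg.minibatch_size}",
            f"{'parameters':<24}{self.network.param_count():,}",
        ]
        for task, loss in self.log.final_losses().items():
            lines.append(f"{'final ' + task + ' loss':<24}{loss:.4f}")
        if self.report is not None:
            r = self.report
            lines += [
                "-" * 54,
                f"{'micro P/R/F':<24}"
                f"{round_half_up(r.micro_p):.2f} / {round_half_up(r.micro_r):.2f} / "
                f"{round_half_up(r.micro_f):.2f}",
                f"{'macro F':<24}{round_half_up(r.macro_f):.2f}",
                f"{'entity accuracy':<24}{round_half_up(r.overall_accuracy):.2f}",
                "-" * 54,
                render_report(r, "per-type-table").rstrip("\n"),
            ]
        return "\n".join(lines) + "\n"
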