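"""Desk-scale seeded experiments: the ablation ladder and lr sweeps.

These drive the full pipeline — generate a two-domain synthetic pair,
pre-train Phase 1 on the general corpus, fine-tune each variant on the
target training split, score on a held-out target test split — at sizes
a single CPU core handles in minutes.  The data conditions follow the
generator defaults (general 5,000 / target 500 sentences, vocabulary
overlap 0.7); the network uses a reduced configuration (32-unit layers,
16-unit character encoder, float32) so the mechanism comparison, not the
arithmetic, dominates the runtime.  Variants within one seed share the
generated data, the Phase-1 package and the architecture, so differences
isolate transfer and multitask effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from medtagger.corpus import Corpus
from medtagger.metrics import MetricsReport
from medtagger.network import ModelConfig
from medtagger.synthetic import GeneratorConfig, generate_domain_pair
from medtagger.training import (
    TrainConfig,
    TransferPackage,
    train_general,
    train_variant,
)

logger = logging.getLogger(__name__)


def desk_model_config() -> ModelConfig:
    """The reduced architecture used for desk-scale experiments."""
    return ModelConfig(
        word_embedding_dim=24,
        char_embedding_dim=12,
        char_hidden=16,
        layer_hidden=32,
        dropout_rate=0.5,
        dtype="float32",
    )


def split_corpus(corpus: Corpus, test_fraction: float = 0.2) -> tuple[Corpus, Corpus]:
    """Leading train split, trailing test split (sentences are i.i.d.)."""
    n_test = max(1, int(round(test_fraction * len(corpus))))
    n_train = len(corpus) - n_test
    return (
        Corpus(corpus.sentences[:n_train], corpus.domain_name + "-train"),
        Corpus(corpus.sentences[n_train:], corpus.domain_name + "-test"),
    )


@dataclass
class SeedRun:
    seed: int
    reports: dict[str, MetricsReport]
    package: TransferPackage


@dataclass
class AblationResult:
    runs: list[SeedRun] = field(default_factory=list)

    def micro_f(self, variant: str) -> list[float]:
        return [r.reports[variant].micro_f for r in self.runs]

    def median_micro_f(self, variant: str) -> float:
        return float(np.median(self.micro_f(variant)))

    def variants(self) -> list[str]:
        return list(self.runs[0].reports) if self.runs else []

    def table(self) -> str:
        lines = [f"{'Variant':<10}{'median MicroF':>14}{'median MacroF':>14}{'median Acc':>12}"]
        for v in self.variants():
            mf = self.median_micro_f(v)
            macro = float(np.median([r.reports[v].macro_f for r in self.runs]))
            acc = float(np.median([r.reports[v].overall_accuracy for r in self.runs]))
            lines.append(f"{v:<10}{mf:>14.2f}{macro:>14.2f}{acc:>12.2f}")
        return "\n".join(lines) + "\n"


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _prepare_seed(
    seed: int,
    generator_config: GeneratorConfig | None,
    model_config: ModelConfig,
    phase1_epochs: int,
    minibatch_size: int,
) -> tuple[Corpus, Corpus, Corpus, TransferPackage]:
    gen_cfg = generator_config or GeneratorConfig()
    gen_cfg = GeneratorConfig(
        **{**gen_cfg.__dict__, "seed": seed}
    )
    general, target = generate_domain_pair(gen_cfg)
    train, test = split_corpus(target)
    phase1_cfg = TrainConfig(
        epochs=phase1_epochs, minibatch_size=minibatch_size, seed=seed
    )
    _, package = train_general(general, phase1_cfg, model_config)
    return general, train, test, package


def run_ablation(
    master_seed: int = 0,
    n_seeds: int = 5,
    variants: tuple[str, ...] = ("BRNN", "TBRNN", "MBRNN", "TMBRNN"),
    epochs: int = 30,
    phase1_epochs: int = 3,
    minibatch_size: int = 50,
    generator_config: GeneratorConfig | None = None,
    model_config: ModelConfig | None = None,
    learning_rate: float = 0.01,
) -> AblationResult:
    """Train the requested variants over ``n_seeds`` seeded replicates.

    Each replicate regenerates the domain pair, pre-trains one Phase-1
    package shared by the transfer variants, fine-tunes every variant on
    the target training split (default 30 epochs) and scores NER on the
    held-out target test split.
    """
    model_config = model_config or desk_model_config()
    result = AblationResult()
    for seed in _derive_seeds(master_seed, n_seeds):
        general, train, test, package = _prepare_seed(
            seed, generator_config, model_config, phase1_epochs, minibatch_size
        )
        reports: dict[str, MetricsReport] = {}
        for variant in variants:
            cfg = TrainConfig(
                learning_rate=learning_rate,
                epochs=epochs,
                minibatch_size=minibatch_size,
                seed=seed,
                variant=variant,
            )
            res = train_variant(
                variant,
                None,
                train,
                cfg,
                model_config=model_config,
                package=package if variant in ("TBRNN", "TMBRNN") else None,
                eval_corpus=test,
            )
            reports[variant] = res.report
            logger.info(
                "seed %d %s: MicroF %.2f", seed, variant, res.report.micro_f
            )
        result.runs.append(SeedRun(seed, reports, package))
    return result


def run_lr_sensitivity(
    master_seed: int = 0,
    n_seeds: int = 3,
    learning_rates: tuple[float, ...] = (0.01, 0.0001),
    epochs: int = 30,
    phase1_epochs: int = 3,
    minibatch_size: int = 50,
    generator_config: GeneratorConfig | None = None,
    model_config: ModelConfig | None = None,
) -> dict[float, list[float]]:
    """Fine-tune the full model at several learning rates.

    One Phase-1 package per seed (trained at the default rate) is reused
    across the rates, so the sweep isolates the fine-tuning schedule.
    Returns learning rate → per-seed test MicroF.
    """
    model_config = model_config or desk_model_config()
    out: dict[float, list[float]] = {lr: [] for lr in learning_rates}
    for seed in _derive_seeds(master_seed, n_seeds):
        general, train, test, package = _prepare_seed(
            seed, generator_config, model_config, phase1_epochs, minibatch_size
        )
        for lr in learning_rates:
            cfg = TrainConfig(
                learning_rate=lr,
                epochs=epochs,
                minibatch_size=minibatch_size,
                seed=seed,
                variant="TMBRNN",
            )
            res = train_variant(
                "TMBRNN",
                None,
                train,
                cfg,
                model_config=model_config,
                package=package,
                eval_corpus=test,
            )
            out[lr].append(res.report.micro_f)
            logger.info("seed %d lr %g: MicroF %.2f", seed, lr, res.report.micro_f)
    return out
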