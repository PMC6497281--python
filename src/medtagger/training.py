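"""Two-phase training: general-domain pre-training, transfer, multitask.

Phase 1 trains a shallow bidirectional LSTM tagger (embeddings + one
bidirectional layer + softmax head) on a large general-domain corpus and
packs that layer's input/recurrent weight matrices — the "general
knowledge" — into a :class:`TransferPackage`.

Phase 2 builds the full four-layer tagger on the small target corpus,
initialises its first (transferred) layer from the package, and
fine-tunes everything while strictly alternating minibatch updates
between the POS objective and the NER objective.  Each objective is
per-token cross-entropy against its own softmax head; the transferred
and shared layers receive gradients from both tasks.  Each task keeps
its own Adam state.  The learning rate is multiplied by a decay factor
after every epoch.

The four-variant ablation ladder isolates the two mechanisms:
``BRNN`` (single-task NER, random init), ``TBRNN`` (+ transferred-layer
init), ``MBRNN`` (+ POS multitask), ``TMBRNN`` (both — the full model).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from medtagger.corpus import Corpus, Vocabulary, build_vocabulary
from medtagger.metrics import MetricsReport, evaluate_sequences
from medtagger.network import Batch, ModelConfig, TaggerModel, make_batches

logger = logging.getLogger(__name__)

VARIANTS = ("BRNN", "TBRNN", "MBRNN", "TMBRNN")


@dataclass
class TrainConfig:
    """Optimisation settings.

    Defaults follow the reference schedule: Adam, learning rate 0.01
    decayed ×0.9 after each epoch, 100 epochs, minibatch 50 (use 10 for
    progress-note-sized workloads).  ``transfer_biases`` controls whether
    the transferred layer's biases are copied along with its U/W weight
    matrices (off by default: the transfer rule is stated for U and W
    only).  ``copy_embeddings`` copies Phase-1 embedding vectors for
    words/characters shared with the Phase-1 vocabulary.
    """

    learning_rate: float = 0.01
    lr_decay: float = 0.9
    epochs: int = 100
    minibatch_size: int = 50
    seed: int = 0
    variant: str = "TMBRNN"
    transfer_biases: bool = False
    copy_embeddings: bool = True
    phase1_task: str = "ner"
    patience: int | None = None  # validation-based early stopping, off by default

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be ≥ 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for 0-based ``epoch``: lr₀ · decayᵉ."""
        return self.learning_rate * self.lr_decay**epoch


@dataclass
class EpochRecord:
    epoch: int
    learning_rate: float
    losses: dict[str, float]
    val_micro_f: float | None = None


@dataclass
class TrainingLog:
    records: list[EpochRecord] = field(default_factory=list)

    def append(self, record: EpochRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def final_losses(self) -> dict[str, float]:
        return self.records[-1].losses if self.records else {}

    def to_json(self) -> str:
        return json.dumps([asdict(r) for r in self.records], indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


class Adam:
    """Adam with per-parameter first/second moment estimates.

    One instance per task objective: shared parameters are updated by
    both objectives but each keeps separate moments.
    """

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(
        self,
        params: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
        lr: float,
    ) -> None:
        for name, g in grads.items():
            p = params[name]
            if name not in self.m:
                self.m[name] = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
                self.t[name] = 0
            self.t[name] += 1
            t = self.t[name]
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            m_hat = m / (1 - self.beta1**t)
            v_hat = v / (1 - self.beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TransferPackage:
    """Serialized Phase-1 bidirectional-layer weights (the transferable
    "general knowledge") plus embeddings and provenance.

    ``U_*`` are input-hidden and ``W_*`` hidden-hidden gate-stacked
    matrices for the forward/backward directions; biases ride along but
    are only applied when requested.
    """

    U_fwd: np.ndarray
    W_fwd: np.ndarray
    b_fwd: np.ndarray
    U_bwd: np.ndarray
    W_bwd: np.ndarray
    b_bwd: np.ndarray
    word_emb: np.ndarray
    char_emb: np.ndarray
    words: list[str]
    chars: list[str]
    source_fingerprint: str
    source_config: dict

    def block_shapes(self) -> dict[str, tuple]:
        return {
            "U_fwd": self.U_fwd.shape,
            "W_fwd": self.W_fwd.shape,
            "U_bwd": self.U_bwd.shape,
            "W_bwd": self.W_bwd.shape,
        }

    def save(self, path: str | Path) -> None:
        arrays = {
            k: getattr(self, k)
            for k in ("U_fwd", "W_fwd", "b_fwd", "U_bwd", "W_bwd", "b_bwd", "word_emb", "char_emb")
        }
        arrays["words"] = np.array(self.words, dtype=np.str_)
        arrays["chars"] = np.array(self.chars, dtype=np.str_)
        arrays["meta_json"] = np.array(
            json.dumps(
                {
                    "source_fingerprint": self.source_fingerprint,
                    "source_config": self.source_config,
                }
            ),
            dtype=np.str_,
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TransferPackage":
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(str(arrays["meta_json"]))
        return cls(
            U_fwd=arrays["U_fwd"],
            W_fwd=arrays["W_fwd"],
            b_fwd=arrays["b_fwd"],
            U_bwd=arrays["U_bwd"],
            W_bwd=arrays["W_bwd"],
            b_bwd=arrays["b_bwd"],
            word_emb=arrays["word_emb"],
            char_emb=arrays["char_emb"],
            words=[str(w) for w in arrays["words"]],
            chars=[str(c) for c in arrays["chars"]],
            source_fingerprint=meta["source_fingerprint"],
            source_config=meta["source_config"],
        )


def _train_epochs(
    model: TaggerModel,
    corpus: Corpus,
    config: TrainConfig,
    tasks: Sequence[str],
    val_fn: Callable[[TaggerModel], float] | None = None,
) -> TrainingLog:
    """Shared epoch loop: strictly alternating per-minibatch updates.

    For each minibatch the tasks fire in fixed order (POS then NER when
    both are present), so over any epoch the two update counts are
    equal.  Dropout masks and batch order come from one seeded stream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA17E]))
    optimizers = {task: Adam() for task in tasks}
    params = model.parameters()
    log = TrainingLog()
    best_val = -np.inf
    stale = 0
    for epoch in range(config.epochs):
        lr = config.lr_at_epoch(epoch)
        batches = make_batches(
            corpus, model.vocab, config.minibatch_size, model.config.np_dtype, rng
        )
        sums = {task: 0.0 for task in tasks}
        for batch in batches:
            for task in tasks:
                loss, grads = model.loss_and_grads(
                    batch, task, training=True, rng=rng
                )
                optimizers[task].step(params, grads, lr)
                sums[task] += loss * batch.n_tokens
        n_tokens = corpus.n_tokens
        losses = {task: sums[task] / n_tokens for task in tasks}
        val = val_fn(model) if val_fn is not None else None
        log.append(EpochRecord(epoch, lr, losses, val))
        logger.info(
            "epoch %d lr=%.5f %s", epoch, lr,
            " ".join(f"{t}_loss={v:.4f}" for t, v in losses.items()),
        )
        if config.patience is not None and val is not None:
            if val > best_val + 1e-12:
                best_val, stale = val, 0
            else:
                stale += 1
                if stale >= config.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    return log


def extract_transfer_package(model: TaggerModel) -> TransferPackage:
    layer = model.transferred_layer
    inv_words = sorted(model.vocab.word_to_id, key=model.vocab.word_to_id.get)
    inv_chars = sorted(model.vocab.char_to_id, key=model.vocab.char_to_id.get)
    return TransferPackage(
        U_fwd=layer.fwd.Wx.copy(),
        W_fwd=layer.fwd.Wh.copy(),
        b_fwd=layer.fwd.b.copy(),
        U_bwd=layer.bwd.Wx.copy(),
        W_bwd=layer.bwd.Wh.copy(),
        b_bwd=layer.bwd.b.copy(),
        word_emb=model.word_emb.copy(),
        char_emb=model.char_emb.copy(),
        words=inv_words,
        chars=inv_chars,
        source_fingerprint=model.vocab.fingerprint(),
        source_config=asdict(model.config),
    )


def train_general(
    corpus: Corpus,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    task: str | None = None,
) -> tuple[TaggerModel, TransferPackage]:
    """Phase 1: train the shallow general-domain tagger.

    The network is embeddings + one bidirectional layer + a softmax head
    for ``task`` (NER by default; POS is supported).  Returns the
    trained model and the :class:`TransferPackage` extracted from its
    bidirectional layer.  Same seed ⇒ bit-identical package.
    """
    if len(corpus) == 0:
        raise ValueError("general corpus is empty")
    task = task or config.phase1_task
    if task not in ("pos", "ner"):
        raise ValueError(f"phase-1 task must be 'pos' or 'ner', got {task!r}")
    vocab = build_vocabulary([corpus])
    model = TaggerModel(
        vocab,
        model_config,
        seed=config.seed,
        tasks=(task,),
        trunk_depth=1,
        task_layers=False,
    )
    _train_epochs(model, corpus, config, (task,))
    return model, extract_transfer_package(model)


def initialize_transferred_layer(
    model: TaggerModel,
    package: TransferPackage,
    transfer_biases: bool = False,
) -> TaggerModel:
    """Set the transferred layer's U/W blocks equal to the Phase-1 values.

    Both directions are assigned element-wise; all other parameter blocks
    keep their random initialisation, and the layer remains trainable.
    With ``transfer_biases`` the biases are copied too, making the layer
    reproduce Phase-1 outputs exactly on identical inputs.
    """
    layer = model.transferred_layer
    pairs = [
        ("U_fwd", layer.fwd.Wx, package.U_fwd),
        ("W_fwd", layer.fwd.Wh, package.W_fwd),
        ("U_bwd", layer.bwd.Wx, package.U_bwd),
        ("W_bwd", layer.bwd.Wh, package.W_bwd),
    ]
    if transfer_biases:
        pairs += [
            ("b_fwd", layer.fwd.b, package.b_fwd),
            ("b_bwd", layer.bwd.b, package.b_bwd),
        ]
    for name, dst, src in pairs:
        if dst.shape != src.shape:
            raise ValueError(
                f"transfer shape mismatch for block {name}: "
                f"model {dst.shape} vs package {src.shape}"
            )
    for _, dst, src in pairs:
        dst[...] = src.astype(dst.dtype)
    return model


def copy_shared_embeddings(model: TaggerModel, package: TransferPackage) -> int:
    """Copy Phase-1 embedding vectors for shared words/characters.

    Returns the number of copied word vectors.  Vectors for words unseen
    in Phase 1 keep their random initialisation.
    """
    src_words = {w: i for i, w in enumerate(package.words)}
    n_copied = 0
    for w, i in model.vocab.word_to_id.items():
        j = src_words.get(w)
        if j is not None:
            model.word_emb[i] = package.word_emb[j].astype(model.word_emb.dtype)
            n_copied += 1
    src_chars = {c: i for i, c in enumerate(package.chars)}
    for c, i in model.vocab.char_to_id.items():
        j = src_chars.get(c)
        if j is not None:
            model.char_emb[i] = package.char_emb[j].astype(model.char_emb.dtype)
    return n_copied


def train_multitask(
    model: TaggerModel,
    target_corpus: Corpus,
    config: TrainConfig,
    val_corpus: Corpus | None = None,
) -> tuple[TaggerModel, TrainingLog]:
    """Phase 2: alternating POS/NER fine-tuning on the target corpus."""
    if len(target_corpus) == 0:
        raise ValueError("target corpus is empty")
    missing = [t for t in model.tasks if t not in ("pos", "ner")]
    if missing:
        raise ValueError(f"unsupported tasks: {missing}")
    val_fn = None
    if val_corpus is not None:
        gold = val_corpus.ner_sequences()

        def val_fn(m: TaggerModel) -> float:
            pred = m.predict_tags(val_corpus)
            return evaluate_sequences(gold, pred).micro_f

    log = _train_epochs(model, target_corpus, config, model.tasks, val_fn)
    return model, log


@dataclass
class VariantResult:
    variant: str
    model: TaggerModel
    log: TrainingLog
    report: MetricsReport | None = None
    package: TransferPackage | None = None


def train_variant(
    variant: str,
    general: Corpus | None,
    target: Corpus,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    package: TransferPackage | None = None,
    general_config: TrainConfig | None = None,
    eval_corpus: Corpus | None = None,
) -> VariantResult:
    """Train one rung of the ablation ladder on shared settings.

    BRNN: single-task NER, random init.  TBRNN: single-task NER with the
    transferred layer initialised from Phase 1.  MBRNN: POS+NER
    multitask, random init.  TMBRNN: multitask with transfer — the full
    model.  All variants share the architecture config, so comparisons
    isolate the transfer/multitask mechanisms.  A pre-built ``package``
    skips Phase-1 training for the transfer variants.  If
    ``eval_corpus`` is given the result carries a MetricsReport of
    NER predictions on it.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    uses_transfer = variant in ("TBRNN", "TMBRNN")
    multitask = variant in ("MBRNN", "TMBRNN")
    if uses_transfer and general is None and package is None:
        raise ValueError(f"{variant} requires a general corpus or TransferPackage")
    if not uses_transfer and general is not None:
        warnings.warn(f"{variant} does not use transfer; ignoring general corpus")

    if uses_transfer and package is None:
        package = train_general(general, general_config or config, model_config)[1]

    tasks = ("pos", "ner") if multitask else ("ner",)
    vocab = build_vocabulary([target])
    model = TaggerModel(vocab, model_config, seed=config.seed, tasks=tasks)
    if uses_transfer:
        initialize_transferred_layer(model, package, config.transfer_biases)
        if config.copy_embeddings:
            n = copy_shared_embeddings(model, package)
            logger.info("%s: copied %d shared word vectors", variant, n)

    log = _train_epochs(model, target, config, tasks)
    report = None
    if eval_corpus is not None:
        pred = model.predict_tags(eval_corpus)
        report = evaluate_sequences(eval_corpus.ner_sequences(), pred)
    return VariantResult(variant, model, log, report, package)
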