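"""The neural core: LSTM cells, bidirectional layers, the tagger network.

The recurrent building block is the standard LSTM cell
(input/forget/output gates, tanh candidate).  A bidirectional layer runs
one forward pass left-to-right and one backward pass right-to-left over
the input sequence and combines the two per-position hidden states by
element-wise **sum** — not the more common concatenation — so forward
and backward hidden sizes must match.  The character encoder is the one
exception: it summarises a word by the **concatenation** of the final
forward and final backward states, and that character vector is
concatenated with the word embedding to form the per-token input.

The full tagger stacks, per token:

    word repr (word emb ⊕ char-BiLSTM) → transferred layer → shared
    layer → task layer (POS or NER) → affine projection → softmax

with dropout on each recurrent layer's output during training.  The
first bidirectional layer is called the *transferred* layer because its
input/recurrent weight matrices can be initialised from a model trained
on a general-domain corpus and then fine-tuned.

Everything — forward passes, analytic gradients, Adam updates — is
implemented directly on NumPy arrays; gradients for every parameter
block are exact (they are verified against central finite differences
in the test suite).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from medtagger.corpus import Corpus, Sentence, Vocabulary

TASKS = ("pos", "ner")


@dataclass
class ModelConfig:
    """Architecture sizes.

    Defaults are the full-scale configuration: 300 LSTM cells per hidden
    layer, 150 for the character layer, dropout 0.5.  Word/character
    embedding dimensions (100/50) are conventional choices.  ``dtype``
    selects the arithmetic precision; float64 is the default, float32
    halves memory and roughly doubles throughput for desk experiments.
    """

    word_embedding_dim: int = 100
    char_embedding_dim: int = 50
    char_hidden: int = 150
    layer_hidden: int = 300
    dropout_rate: float = 0.5
    dtype: str = "float64"

    def __post_init__(self) -> None:
        for name in ("word_embedding_dim", "char_embedding_dim", "char_hidden", "layer_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def np_dtype(self) -> np.dtype:
        return np.dtype(self.dtype)

    @property
    def word_repr_dim(self) -> int:
        # word embedding ⊕ concatenated final char states
        return self.word_embedding_dim + 2 * self.char_hidden


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype: np.dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class LSTMDirection:
    """One direction of an LSTM layer.

    Gate parameters are stacked column-wise in order input, forget,
    output, candidate: ``Wx`` is (D, 4H), ``Wh`` is (H, 4H), ``b`` is
    (4H,).  ``Wx``/``Wh`` realise the input-hidden matrix U and the
    hidden-hidden matrix W of the recurrent step; the initial hidden and
    cell states are zero.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator, dtype: np.dtype):
        self.d_in = d_in
        self.d_hidden = d_hidden
        self.Wx = _glorot(rng, (d_in, 4 * d_hidden), dtype)
        self.Wh = _glorot(rng, (d_hidden, 4 * d_hidden), dtype)
        self.b = np.zeros(4 * d_hidden, dtype=dtype)
        # forget-gate bias 1: standard trick to ease gradient flow early on
        self.b[d_hidden : 2 * d_hidden] = 1.0

    def params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def step(
        self, x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, tuple]:
        """One recurrent step h_t = H(U x_t + W h_{t-1} + b) with H the
        LSTM update; returns (h, c, gate cache)."""
        H = self.d_hidden
        a = x @ self.Wx + h_prev @ self.Wh + self.b
        i = _sigmoid(a[..., :H])
        f = _sigmoid(a[..., H : 2 * H])
        o = _sigmoid(a[..., 2 * H : 3 * H])
        g = np.tanh(a[..., 3 * H :])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        return h, c, (i, f, o, g, tc, h_prev, c_prev)

    def forward(
        self, X: np.ndarray, mask: np.ndarray, reverse: bool = False
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Run over a padded batch X (B, T, D) with mask (B, T).

        Padded positions pass states through unchanged, so the final
        state equals the state at the last valid position.  Returns
        (per-position states (B, T, H), final state (B, H), cache).
        """
        B, T, _ = X.shape
        H = self.d_hidden
        h = np.zeros((B, H), dtype=X.dtype)
        c = np.zeros((B, H), dtype=X.dtype)
        H_seq = np.zeros((B, T, H), dtype=X.dtype)
        caches: list[tuple] = [None] * T
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            h_new, c_new, cache = self.step(X[:, t], h, c)
            m = mask[:, t : t + 1]
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            H_seq[:, t] = h
            caches[t] = cache
        info = {"caches": caches, "reverse": reverse, "X": X, "mask": mask}
        return H_seq, h, info

    def backward(
        self,
        dH_seq: np.ndarray | None,
        dh_final: np.ndarray | None,
        info: dict,
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Backprop through :meth:`forward`; returns (dX, param grads)."""
        X, mask = info["X"], info["mask"]
        caches = info["caches"]
        B, T, _ = X.shape
        H = self.d_hidden
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh = (
            dh_final.copy()
            if dh_final is not None
            else np.zeros((B, H), dtype=X.dtype)
        )
        dc = np.zeros((B, H), dtype=X.dtype)
        order = range(T) if info["reverse"] else range(T - 1, -1, -1)
        for t in order:
            if dH_seq is not None:
                dh = dh + dH_seq[:, t]
            i, f, o, g, tc, h_prev, c_prev = caches[t]
            m = mask[:, t : t + 1]
            dh_new = dh * m
            dh_carry = dh * (1.0 - m)
            dc_new = dc * m
            dc_carry = dc * (1.0 - m)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dc = dc_new * f + dc_carry
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g * g),
                ],
                axis=-1,
            )
            dWx += X[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t] += da @ self.Wx.T
            dh = da @ self.Wh.T + dh_carry
        return dX, {"Wx": dWx, "Wh": dWh, "b": db}


class BiLSTMLayer:
    """A bidirectional LSTM layer.

    ``mode='sum'`` emits per-position element-wise sums of the two
    direction states (the sentence-level layers).  ``mode='final_concat'``
    emits one vector per sequence: the concatenation of the final
    forward and final backward states (the character encoder).
    """

    def __init__(
        self,
        d_in: int,
        d_hidden: int,
        rng: np.random.Generator,
        dtype: np.dtype,
        mode: str = "sum",
    ):
        if mode not in ("sum", "final_concat"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.d_hidden = d_hidden
        self.fwd = LSTMDirection(d_in, d_hidden, rng, dtype)
        self.bwd = LSTMDirection(d_in, d_hidden, rng, dtype)

    @property
    def d_out(self) -> int:
        return self.d_hidden if self.mode == "sum" else 2 * self.d_hidden

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for dname, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            for pname, arr in d.params().items():
                out[f"{dname}.{pname}"] = arr
        return out

    def forward(self, X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
        Hf, hf_final, info_f = self.fwd.forward(X, mask, reverse=False)
        Hb, hb_final, info_b = self.bwd.forward(X, mask, reverse=True)
        if self.mode == "sum":
            out = Hf + Hb
        else:
            out = np.concatenate([hf_final, hb_final], axis=-1)
        return out, {"f": info_f, "b": info_b}

    def backward(self, d_out: np.ndarray, info: dict) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        H = self.d_hidden
        if self.mode == "sum":
            dXf, gf = self.fwd.backward(d_out, None, info["f"])
            dXb, gb = self.bwd.backward(d_out, None, info["b"])
        else:
            dXf, gf = self.fwd.backward(None, d_out[..., :H], info["f"])
            dXb, gb = self.bwd.backward(None, d_out[..., H:], info["b"])
        grads = {f"fwd.{k}": v for k, v in gf.items()}
        grads.update({f"bwd.{k}": v for k, v in gb.items()})
        return dXf + dXb, grads


class Projection:
    """Affine hidden→label map y_t = V h_t + b_y feeding the softmax."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype: np.dtype):
        self.V = _glorot(rng, (d_in, d_out), dtype)
        self.b = np.zeros(d_out, dtype=dtype)

    def params(self) -> dict[str, np.ndarray]:
        return {"V": self.V, "b": self.b}

    def forward(self, H: np.ndarray) -> np.ndarray:
        return H @ self.V + self.b

    def backward(self, d_logits: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, dict]:
        dV = H.reshape(-1, H.shape[-1]).T @ d_logits.reshape(-1, d_logits.shape[-1])
        db = d_logits.reshape(-1, d_logits.shape[-1]).sum(axis=0)
        dH = d_logits @ self.V.T
        return dH, {"V": dV, "b": db}


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Batching


@dataclass
class Batch:
    """A padded minibatch of encoded sentences.

    ``token_uid`` indexes each (sentence, position) into the batch's
    unique-word table, so the character encoder runs once per distinct
    word form instead of once per token.
    """

    words: np.ndarray  # (B, T) word ids, PAD=0
    mask: np.ndarray  # (B, T) 1.0 for real tokens
    pos: np.ndarray  # (B, T) POS label ids
    ner: np.ndarray  # (B, T) NER label ids
    token_uid: np.ndarray  # (B, T) index into unique-word table
    uw_chars: np.ndarray  # (Nu, Lc) char ids, PAD=0
    uw_mask: np.ndarray  # (Nu, Lc)
    sentence_indices: list[int]  # positions in the source corpus

    @property
    def n_tokens(self) -> int:
        return int(self.mask.sum())

    def labels(self, task: str) -> np.ndarray:
        if task == "pos":
            return self.pos
        if task == "ner":
            return self.ner
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def make_batch(
    encoded: Sequence[dict], indices: Sequence[int], dtype: np.dtype
) -> Batch:
    B = len(encoded)
    T = max(len(e["words"]) for e in encoded)
    words = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T), dtype=dtype)
    pos = np.zeros((B, T), dtype=np.int64)
    ner = np.zeros((B, T), dtype=np.int64)
    token_uid = np.zeros((B, T), dtype=np.int64)
    uniq: dict[tuple[int, ...], int] = {}
    uw: list[tuple[int, ...]] = []
    for b, e in enumerate(encoded):
        n = len(e["words"])
        words[b, :n] = e["words"]
        mask[b, :n] = 1.0
        pos[b, :n] = e["pos"]
        ner[b, :n] = e["ner"]
        for t, chars in enumerate(e["chars"]):
            key = tuple(chars)
            if key not in uniq:
                uniq[key] = len(uw)
                uw.append(key)
            token_uid[b, t] = uniq[key]
    Lc = max(len(w) for w in uw)
    uw_chars = np.zeros((len(uw), Lc), dtype=np.int64)
    uw_mask = np.zeros((len(uw), Lc), dtype=dtype)
    for i, w in enumerate(uw):
        uw_chars[i, : len(w)] = w
        uw_mask[i, : len(w)] = 1.0
    return Batch(words, mask, pos, ner, token_uid, uw_chars, uw_mask, list(indices))


def make_batches(
    corpus: Corpus,
    vocab: Vocabulary,
    batch_size: int,
    dtype: np.dtype,
    rng: np.random.Generator | None = None,
) -> list[Batch]:
    """Bucket sentences by length, pad, and batch.

    Sentences are sorted by length before chunking so padding stays
    small; with an ``rng`` the batch order is then shuffled (the order
    within a batch is not — determinism under a fixed seed).
    """
    encoded = [vocab.encode_sentence(s) for s in corpus.sentences]
    order = sorted(range(len(encoded)), key=lambda i: len(encoded[i]["words"]))
    chunks = [order[i : i + batch_size] for i in range(0, len(order), batch_size)]
    if rng is not None and len(chunks) > 1:
        rng.shuffle(chunks)
    return [make_batch([encoded[i] for i in idx], idx, dtype) for idx in chunks]


# ---------------------------------------------------------------------------
# The tagger


class TaggerModel:
    """The transfer + multitask bidirectional LSTM tagger.

    ``trunk_depth=2`` builds the full architecture (transferred layer +
    shared layer + one bidirectional task layer per task head);
    ``trunk_depth=1`` with a single head builds the shallow
    general-domain network used for pre-training (embedding + one
    bidirectional layer + output projection).

    Parameters are exposed as a flat name → array mapping
    (:meth:`parameters`), with names like ``transferred.fwd.Wx`` or
    ``ner.proj.V``; gradient dictionaries share the same keys.
    """

    def __init__(
        self,
        vocab: Vocabulary,
        config: ModelConfig | None = None,
        seed: int = 0,
        tasks: Sequence[str] = TASKS,
        trunk_depth: int = 2,
        task_layers: bool = True,
    ):
        self.vocab = vocab
        self.config = config or ModelConfig()
        self.seed = seed
        self.tasks = tuple(tasks)
        self.trunk_depth = trunk_depth
        self.task_layers = task_layers
        cfg = self.config
        dt = cfg.np_dtype
        rng = np.random.default_rng(np.random.SeedSequence(seed))

        self.word_emb = (
            rng.uniform(-1, 1, size=(vocab.n_words, cfg.word_embedding_dim))
            * np.sqrt(3.0 / cfg.word_embedding_dim)
        ).astype(dt)
        self.char_emb = (
            rng.uniform(-1, 1, size=(vocab.n_chars, cfg.char_embedding_dim))
            * np.sqrt(3.0 / cfg.char_embedding_dim)
        ).astype(dt)
        self.word_emb[0] = 0.0
        self.char_emb[0] = 0.0

        self.char_layer = BiLSTMLayer(
            cfg.char_embedding_dim, cfg.char_hidden, rng, dt, mode="final_concat"
        )
        self.trunk: list[BiLSTMLayer] = []
        d_in = cfg.word_repr_dim
        for _ in range(trunk_depth):
            self.trunk.append(BiLSTMLayer(d_in, cfg.layer_hidden, rng, dt, mode="sum"))
            d_in = cfg.layer_hidden
        self.heads: dict[str, tuple[BiLSTMLayer | None, Projection]] = {}
        for task in self.tasks:
            n_labels = vocab.n_pos if task == "pos" else vocab.n_ner
            layer = (
                BiLSTMLayer(d_in, cfg.layer_hidden, rng, dt, mode="sum")
                if task_layers
                else None
            )
            proj_in = cfg.layer_hidden if task_layers else d_in
            self.heads[task] = (layer, Projection(proj_in, n_labels, rng, dt))

    # -- parameter registry -------------------------------------------------

    @property
    def layer_names(self) -> list[str]:
        return ["transferred", "shared"][: self.trunk_depth]

    @property
    def transferred_layer(self) -> BiLSTMLayer:
        return self.trunk[0]

    def parameters(self) -> dict[str, np.ndarray]:
        out = {"word_emb": self.word_emb, "char_emb": self.char_emb}
        for k, v in self.char_layer.params().items():
            out[f"char.{k}"] = v
        for name, layer in zip(self.layer_names, self.trunk):
            for k, v in layer.params().items():
                out[f"{name}.{k}"] = v
        for task, (layer, proj) in self.heads.items():
            if layer is not None:
                for k, v in layer.params().items():
                    out[f"{task}.layer.{k}"] = v
            for k, v in proj.params().items():
                out[f"{task}.proj.{k}"] = v
        return out

    def set_parameter(self, name: str, value: np.ndarray) -> None:
        current = self.parameters()[name]
        if current.shape != value.shape:
            raise ValueError(
                f"shape mismatch for {name}: have {current.shape}, got {value.shape}"
            )
        current[...] = value.astype(current.dtype)

    def param_count(self, include_embeddings: bool = True) -> int:
        skip = () if include_embeddings else ("word_emb", "char_emb")
        return sum(v.size for k, v in self.parameters().items() if k not in skip)

    def task_param_names(self, task: str) -> list[str]:
        """Parameters touched by one task's objective (shared + that head)."""
        names = []
        for k in self.parameters():
            head_owner = k.split(".")[0]
            if head_owner in self.tasks and head_owner != task:
                continue
            names.append(k)
        return names

    # -- forward / backward -------------------------------------------------

    def _word_repr(
        self, batch: Batch, training: bool, rng: np.random.Generator | None
    ) -> tuple[np.ndarray, dict]:
        cfg = self.config
        E = self.char_emb[batch.uw_chars]  # (Nu, Lc, Dc)
        char_vec_u, char_info = self.char_layer.forward(E, batch.uw_mask)
        drop_char = self._dropout_mask(char_vec_u.shape, training, rng)
        if drop_char is not None:
            char_vec_u = char_vec_u * drop_char
        char_vec = char_vec_u[batch.token_uid]  # (B, T, 2Hc)
        W = self.word_emb[batch.words]  # (B, T, Dw)
        X = np.concatenate([W, char_vec], axis=-1)
        cache = {
            "char_info": char_info,
            "char_E": E,
            "char_vec_u": char_vec_u,
            "drop_char": drop_char,
            "n_unique": char_vec_u.shape[0],
        }
        return X, cache

    def _dropout_mask(
        self, shape: tuple, training: bool, rng: np.random.Generator | None
    ) -> np.ndarray | None:
        rate = self.config.dropout_rate
        if not training or rate == 0.0:
            return None
        if rng is None:
            raise ValueError("training-mode forward pass needs an RNG for dropout")
        keep = 1.0 - rate
        return (
            (rng.random(shape) < keep).astype(self.config.np_dtype) / keep
        )

    def _forward(
        self,
        batch: Batch,
        task: str,
        training: bool,
        rng: np.random.Generator | None,
    ) -> tuple[np.ndarray, dict]:
        if task not in self.heads:
            raise ValueError(f"unknown task {task!r}; model has {sorted(self.heads)}")
        X, cache = self._word_repr(batch, training, rng)
        cache["X0"] = X
        cache["trunk"] = []
        H = X
        for layer in self.trunk:
            H_out, info = layer.forward(H, batch.mask)
            drop = self._dropout_mask(H_out.shape, training, rng)
            if drop is not None:
                H_out = H_out * drop
            cache["trunk"].append({"in": H, "info": info, "drop": drop})
            H = H_out
        head_layer, proj = self.heads[task]
        if head_layer is not None:
            H_out, info = head_layer.forward(H, batch.mask)
            drop = self._dropout_mask(H_out.shape, training, rng)
            if drop is not None:
                H_out = H_out * drop
            cache["head"] = {"in": H, "info": info, "drop": drop}
            H = H_out
        cache["H_final"] = H
        logits = proj.forward(H)
        return logits, cache

    def forward_pass(
        self,
        batch: Batch,
        task: str,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Per-token label distributions (B, T, n_labels) for ``task``."""
        logits, _ = self._forward(batch, task, training, rng)
        return softmax(logits)

    def loss(self, batch: Batch, task: str) -> float:
        probs = self.forward_pass(batch, task, training=False)
        return self._ce(probs, batch.labels(task), batch.mask)

    @staticmethod
    def _ce(probs: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
        B, T, _ = probs.shape
        p = probs[np.arange(B)[:, None], np.arange(T)[None, :], labels]
        logp = np.log(np.maximum(p, 1e-300))
        return float(-(logp * mask).sum() / mask.sum())

    def loss_and_grads(
        self,
        batch: Batch,
        task: str,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean masked cross-entropy and its gradient for every block the
        task touches (embeddings, char layer, trunk, the task's head)."""
        logits, cache = self._forward(batch, task, training, rng)
        probs = softmax(logits)
        labels = batch.labels(task)
        mask = batch.mask
        loss = self._ce(probs, labels, mask)

        n_valid = mask.sum()
        B, T, L = probs.shape
        d_logits = probs.copy()
        d_logits[np.arange(B)[:, None], np.arange(T)[None, :], labels] -= 1.0
        d_logits *= (mask / n_valid)[..., None]

        grads: dict[str, np.ndarray] = {}
        head_layer, proj = self.heads[task]
        dH, proj_grads = proj.backward(d_logits, cache["H_final"])
        for k, v in proj_grads.items():
            grads[f"{task}.proj.{k}"] = v
        if head_layer is not None:
            hc = cache["head"]
            if hc["drop"] is not None:
                dH = dH * hc["drop"]
            dH, layer_grads = head_layer.backward(dH, hc["info"])
            for k, v in layer_grads.items():
                grads[f"{task}.layer.{k}"] = v
        for name, layer, tc in zip(
            reversed(self.layer_names), reversed(self.trunk), reversed(cache["trunk"])
        ):
            if tc["drop"] is not None:
                dH = dH * tc["drop"]
            dH, layer_grads = layer.backward(dH, tc["info"])
            for k, v in layer_grads.items():
                grads[f"{name}.{k}"] = v

        # split word-representation gradient back into embedding channels
        Dw = self.config.word_embedding_dim
        dW_emb_vec = dH[..., :Dw] * mask[..., None]
        d_char_vec = dH[..., Dw:] * mask[..., None]

        d_word_emb = np.zeros_like(self.word_emb)
        np.add.at(d_word_emb, batch.words.ravel(), dW_emb_vec.reshape(-1, Dw))

        dU = np.zeros(
            (cache["n_unique"], d_char_vec.shape[-1]), dtype=d_char_vec.dtype
        )
        np.add.at(
            dU, batch.token_uid.ravel(), d_char_vec.reshape(-1, d_char_vec.shape[-1])
        )
        if cache["drop_char"] is not None:
            dU = dU * cache["drop_char"]
        dE, char_grads = self.char_layer.backward(dU, cache["char_info"])
        dE = dE * batch.uw_mask[..., None]
        for k, v in char_grads.items():
            grads[f"char.{k}"] = v
        d_char_emb = np.zeros_like(self.char_emb)
        np.add.at(
            d_char_emb, batch.uw_chars.ravel(), dE.reshape(-1, dE.shape[-1])
        )
        grads["word_emb"] = d_word_emb
        grads["char_emb"] = d_char_emb
        return loss, grads

    # -- prediction ---------------------------------------------------------

    def predict_tags(self, corpus: Corpus, batch_size: int = 64, task: str = "ner") -> list[list[str]]:
        """Argmax tag sequences for every sentence, in corpus order."""
        decode = (
            self.vocab.id_to_ner if task == "ner" else self.vocab.id_to_pos
        )
        out: dict[int, list[str]] = {}
        for batch in make_batches(
            corpus, self.vocab, batch_size, self.config.np_dtype
        ):
            probs = self.forward_pass(batch, task, training=False)
            ids = probs.argmax(axis=-1)
            for row, sent_idx in enumerate(batch.sentence_indices):
                n = int(batch.mask[row].sum())
                out[sent_idx] = [decode[int(i)] for i in ids[row, :n]]
        return [out[i] for i in range(len(corpus))]

    # -- persistence --------------------------------------------------------

    def _meta(self) -> dict:
        return {
            "config": asdict(self.config),
            "seed": self.seed,
            "tasks": list(self.tasks),
            "trunk_depth": self.trunk_depth,
            "task_layers": self.task_layers,
            "vocab_fingerprint": self.vocab.fingerprint(),
        }

    def save(self, path: str | Path) -> None:
        """Serialize all parameter blocks plus config and vocabulary into
        one archive; round-trips bit-exactly."""
        arrays = {f"param:{k}": v for k, v in self.parameters().items()}
        arrays.update(self.vocab.to_arrays())
        arrays["meta_json"] = np.array(json.dumps(self._meta()), dtype=np.str_)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(str(arrays["meta_json"]))
        vocab = Vocabulary.from_arrays(arrays)
        model = cls(
            vocab,
            ModelConfig(**meta["config"]),
            seed=meta["seed"],
            tasks=tuple(meta["tasks"]),
            trunk_depth=meta["trunk_depth"],
            task_layers=meta["task_layers"],
        )
        if meta["vocab_fingerprint"] != vocab.fingerprint():
            raise ValueError("vocabulary fingerprint mismatch in checkpoint")
        for name in model.parameters():
            model.set_parameter(name, arrays[f"param:{name}"])
        return model


# ---------------------------------------------------------------------------
# Free-function views of the core operations (used directly in tests and
# by callers that want the primitive without a full model).


def recurrent_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    direction: LSTMDirection,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM recurrent step; returns (h, c)."""
    h, c, _ = direction.step(x, h_prev, c_prev)
    return h, c


def bidirectional_layer(inputs: np.ndarray, layer: BiLSTMLayer) -> np.ndarray:
    """Run one bidirectional layer over a single unpadded sequence (T, D).

    Returns (T, H) sums of the direction states for 'sum' layers, or the
    (2H,) final-state concatenation for 'final_concat' layers.
    """
    if inputs.ndim != 2 or inputs.shape[0] == 0:
        raise ValueError("inputs must be a non-empty (T, D) sequence")
    X = inputs[None]
    mask = np.ones((1, X.shape[1]), dtype=X.dtype)
    out, _ = layer.forward(X, mask)
    return out[0]


def encode_characters(
    char_ids: Sequence[int], char_emb: np.ndarray, char_layer: BiLSTMLayer
) -> np.ndarray:
    """Character-level word vector: final fwd ⊕ final bwd state."""
    if len(char_ids) == 0:
        raise ValueError("cannot encode an empty word")
    E = char_emb[np.asarray(char_ids, dtype=np.int64)]
    return bidirectional_layer(E, char_layer)
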