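"""Column-format tagged corpora: reading, writing, vocabularies, BIO spans.

The on-disk format is the usual CoNLL-style layout — one token per line,
whitespace-separated columns (surface form, POS tag, BIO entity tag),
sentences separated by blank lines, UTF-8.  Entity mentions are encoded
with the BIO scheme: ``B-<type>`` opens a mention, ``I-<type>`` continues
it, ``O`` marks non-entity tokens.  All span coordinates are 0-based,
half-open token indices.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The five clinical entity types scored in the evaluation tables.
DEFAULT_ENTITY_TYPES: tuple[str, ...] = (
    "disease",
    "symptom",
    "treatment",
    "test",
    "disease_group",
)

PAD_ID = 0
UNK_ID = 1
PAD_TOKEN = "<PAD>"
UNK_TOKEN = "<UNK>"


class CorpusFormatError(ValueError):
    """Raised for malformed column files (missing columns, bad labels)."""


@dataclass(frozen=True)
class Token:
    """A single token with its POS tag and BIO entity tag."""

    surface: str
    pos: str
    ner: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise ValueError("sentence must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    @property
    def pos_tags(self) -> list[str]:
        return [t.pos for t in self.tokens]

    @property
    def ner_tags(self) -> list[str]:
        return [t.ner for t in self.tokens]


@dataclass
class Corpus:
    sentences: list[Sentence] = field(default_factory=list)
    domain_name: str = ""

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def ner_sequences(self) -> list[list[str]]:
        return [s.ner_tags for s in self.sentences]

    def mentions(self) -> list["EntityMention"]:
        out: list[EntityMention] = []
        for i, sent in enumerate(self.sentences):
            out.extend(decode_entities(sent.ner_tags, sentence_index=i))
        return out


@dataclass(frozen=True, order=True)
class EntityMention:
    """An entity occurrence: type plus half-open token span in a sentence."""

    sentence_index: int
    start: int
    end: int
    entity_type: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def repair_bio(tags: Sequence[str]) -> tuple[list[str], int]:
    """Repair a BIO sequence in place of raising on malformed input.

    An ``I-t`` that does not continue a ``B-t``/``I-t`` of the same type
    (at sentence start, after ``O``, or after a different type) is
    rewritten to ``B-t`` — the conventional conlleval leniency, which
    makes span decoding a total function.  Returns the repaired sequence
    and the number of rewrites.
    """
    repaired: list[str] = []
    n_fixed = 0
    prev_type: str | None = None
    for tag in tags:
        if tag.startswith("I-"):
            t = tag[2:]
            if prev_type != t:
                repaired.append("B-" + t)
                n_fixed += 1
            else:
                repaired.append(tag)
            prev_type = t
        elif tag.startswith("B-"):
            repaired.append(tag)
            prev_type = tag[2:]
        else:
            repaired.append(tag)
            prev_type = None
    return repaired, n_fixed


def decode_entities(
    tags: Sequence[str], sentence_index: int = 0
) -> list[EntityMention]:
    """Decode a BIO tag sequence into entity mentions.

    Maximal runs ``B-t (I-t)*`` become one mention of type ``t`` with a
    half-open token span.  Malformed ``I-t`` openings are first repaired
    (treated as ``B-t``), so decoding never fails.  Output is sorted by
    start position.
    """
    repaired, _ = repair_bio(tags)
    mentions: list[EntityMention] = []
    start: int | None = None
    etype: str | None = None
    for i, tag in enumerate(repaired):
        if tag.startswith("B-"):
            if start is not None:
                mentions.append(EntityMention(sentence_index, start, i, etype))
            start, etype = i, tag[2:]
        elif tag.startswith("I-"):
            pass  # repaired sequence guarantees continuation of current run
        else:
            if start is not None:
                mentions.append(EntityMention(sentence_index, start, i, etype))
            start, etype = None, None
    if start is not None:
        mentions.append(EntityMention(sentence_index, start, len(repaired), etype))
    return mentions


def mentions_to_bio(mentions: Iterable[EntityMention], length: int) -> list[str]:
    """Encode non-overlapping mentions as a BIO tag sequence of ``length``."""
    tags = ["O"] * length
    for m in sorted(mentions):
        if m.end > length:
            raise ValueError(f"mention {m} exceeds sentence length {length}")
        if any(t != "O" for t in tags[m.start : m.end]):
            raise ValueError(f"mention {m} overlaps a previous mention")
        tags[m.start] = "B-" + m.entity_type
        for i in range(m.start + 1, m.end):
            tags[i] = "I-" + m.entity_type
    return tags


def read_conll(
    path: str | Path,
    columns: Sequence[str] = ("token", "pos", "ner"),
    domain_name: str = "",
) -> Corpus:
    """Read a CoNLL-style column file into a :class:`Corpus`.

    ``columns`` names the meaning of each whitespace-separated column and
    must include ``token``, ``pos`` and ``ner``.  Malformed BIO sequences
    are repaired (see :func:`repair_bio`) with a logged warning count.
    An empty file yields an empty corpus.
    """
    path = Path(path)
    idx = {name: i for i, name in enumerate(columns)}
    for required in ("token", "pos", "ner"):
        if required not in idx:
            raise ValueError(f"column spec must include {required!r}")
    n_cols = len(columns)

    sentences: list[Sentence] = []
    rows: list[tuple[str, str, str]] = []
    n_repairs = 0

    def flush() -> None:
        nonlocal n_repairs, rows
        if not rows:
            return
        tags, fixed = repair_bio([r[2] for r in rows])
        n_repairs += fixed
        sentences.append(
            Sentence(tuple(Token(r[0], r[1], t) for r, t in zip(rows, tags)))
        )
        rows = []

    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            parts = line.split()
            if len(parts) < n_cols:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected ≥{n_cols} columns, got {len(parts)}"
                )
            rows.append((parts[idx["token"]], parts[idx["pos"]], parts[idx["ner"]]))
    flush()

    if n_repairs:
        logger.warning("%s: repaired %d malformed BIO tags", path, n_repairs)
    corpus = Corpus(sentences, domain_name=domain_name or path.stem)
    corpus.n_bio_repairs = n_repairs  # type: ignore[attr-defined]
    return corpus


def write_conll(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as tab-separated token/POS/NER columns.

    Round-trips exactly through :func:`read_conll`.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in corpus.sentences:
            for tok in sent.tokens:
                fh.write(f"{tok.surface}\t{tok.pos}\t{tok.ner}\n")
            fh.write("\n")


def bio_label_set(entity_types: Sequence[str]) -> list[str]:
    """The full BIO closure over ``entity_types``: O plus B-/I- per type."""
    labels = ["O"]
    for t in entity_types:
        labels.append("B-" + t)
        labels.append("I-" + t)
    return labels


@dataclass
class Vocabulary:
    """Bidirectional id mappings for words, characters, POS and NER labels.

    Word and character maps reserve id 0 for padding and id 1 for
    unknowns; rare words (below the ``min_word_freq`` used at build time)
    are absent from the map and encode to the unknown id.  The NER map is
    the complete BIO closure of the configured entity types —
    ``2 * n_types + 1`` labels.
    """

    word_to_id: dict[str, int]
    char_to_id: dict[str, int]
    pos_to_id: dict[str, int]
    ner_to_id: dict[str, int]
    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES

    def __post_init__(self) -> None:
        self.id_to_ner = {i: t for t, i in self.ner_to_id.items()}
        self.id_to_pos = {i: t for t, i in self.pos_to_id.items()}

    @property
    def n_words(self) -> int:
        return len(self.word_to_id)

    @property
    def n_chars(self) -> int:
        return len(self.char_to_id)

    @property
    def n_pos(self) -> int:
        return len(self.pos_to_id)

    @property
    def n_ner(self) -> int:
        return len(self.ner_to_id)

    def encode_word(self, word: str) -> int:
        return self.word_to_id.get(word, UNK_ID)

    def encode_chars(self, word: str) -> list[int]:
        return [self.char_to_id.get(c, UNK_ID) for c in word]

    def encode_sentence(self, sentence: Sentence) -> dict[str, list]:
        return {
            "words": [self.encode_word(w) for w in sentence.surfaces],
            "chars": [self.encode_chars(w) for w in sentence.surfaces],
            "pos": [self.pos_to_id[p] for p in sentence.pos_tags],
            "ner": [self.ner_to_id[t] for t in sentence.ner_tags],
        }

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for name, mapping in (
            ("word", self.word_to_id),
            ("char", self.char_to_id),
            ("pos", self.pos_to_id),
            ("ner", self.ner_to_id),
        ):
            h.update(name.encode())
            for k in sorted(mapping):
                h.update(f"{k}\x00{mapping[k]}\x01".encode())
        return h.hexdigest()

    def to_arrays(self) -> dict[str, np.ndarray]:
        def pack(mapping: dict[str, int]) -> np.ndarray:
            items = sorted(mapping.items(), key=lambda kv: kv[1])
            return np.array([k for k, _ in items], dtype=np.str_)

        return {
            "vocab_words": pack(self.word_to_id),
            "vocab_chars": pack(self.char_to_id),
            "vocab_pos": pack(self.pos_to_id),
            "vocab_ner": pack(self.ner_to_id),
            "vocab_entity_types": np.array(self.entity_types, dtype=np.str_),
        }

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "Vocabulary":
        def unpack(arr: np.ndarray) -> dict[str, int]:
            return {str(w): i for i, w in enumerate(arr)}

        return cls(
            word_to_id=unpack(arrays["vocab_words"]),
            char_to_id=unpack(arrays["vocab_chars"]),
            pos_to_id=unpack(arrays["vocab_pos"]),
            ner_to_id=unpack(arrays["vocab_ner"]),
            entity_types=tuple(str(t) for t in arrays["vocab_entity_types"]),
        )


def build_vocabulary(
    corpora: Sequence[Corpus],
    min_word_freq: int = 1,
    entity_types: Sequence[str] = DEFAULT_ENTITY_TYPES,
) -> Vocabulary:
    """Build word/char/POS/NER id maps from training corpora.

    Words seen fewer than ``min_word_freq`` times are dropped from the
    word map and encode to the unknown id; the character map covers every
    character observed in training surfaces.  Id assignment follows first
    occurrence in corpus order, so the mapping is deterministic.
    """
    if not corpora or all(len(c) == 0 for c in corpora):
        raise ValueError("at least one non-empty corpus required")

    word_freq: Counter[str] = Counter()
    chars: dict[str, None] = {}
    pos_tags: dict[str, None] = {}
    for corpus in corpora:
        for sent in corpus:
            for tok in sent.tokens:
                word_freq[tok.surface] += 1
                for c in tok.surface:
                    chars.setdefault(c, None)
                pos_tags.setdefault(tok.pos, None)

    word_to_id = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
    for corpus in corpora:
        for sent in corpus:
            for tok in sent.tokens:
                w = tok.surface
                if w not in word_to_id and word_freq[w] >= min_word_freq:
                    word_to_id[w] = len(word_to_id)

    char_to_id = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
    for c in chars:
        char_to_id[c] = len(char_to_id)

    pos_to_id = {p: i for i, p in enumerate(pos_tags)}
    ner_to_id = {t: i for i, t in enumerate(bio_label_set(entity_types))}
    return Vocabulary(word_to_id, char_to_id, pos_to_id, ner_to_id, tuple(entity_types))


def read_word2vec_text(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Read a textual word2vec embedding table.

    Expects a header line ``<count> <dim>`` followed by ``word v1 … vdim``
    lines.  Returns (word → vector mapping, dimension).
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusFormatError(f"{path}: expected 'count dim' header")
        count, dim = int(header[0]), int(header[1])
        table: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected {dim + 1} fields, got {len(parts)}"
                )
            table[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(table) != count:
        logger.warning(
            "%s: header promised %d vectors, found %d", path, count, len(table)
        )
    return table, dim
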