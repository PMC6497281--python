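"""Seeded generator for related two-domain tagged corpora.

Emulates the transfer + multitask setting: a large "general" corpus and
a small "target" (EMR-like) corpus that share a configurable fraction of
their vocabulary and entity phrases.  Every sentence carries POS tags
(a deterministic function of each word's lexical class) and BIO entity
tags over five clinical entity types with multi-token mentions, so the
POS auxiliary task is learnable and span-level NER evaluation is
meaningful without any real data.

Generation is template-draw → slot-fill → tag: sentence templates are
sequences of slots naming either a POS class or an entity slot; entity
slots are filled with multi-token phrases from per-type lexicons, with
mention lengths drawn from an explicit distribution.  No grammar is
learned.  Word forms are synthetic syllable strings whose suffixes carry
class information, giving the character encoder a real signal; the
script is deliberately generic rather than Chinese — the character
channel works the same way regardless of script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from medtagger.corpus import (
    DEFAULT_ENTITY_TYPES,
    Corpus,
    Sentence,
    Token,
    decode_entities,
    mentions_to_bio,
)

# POS tag per lexical class; entity-phrase tokens are tagged as nouns.
POS_CLASSES: dict[str, str] = {
    "noun": "NN",
    "verb": "VV",
    "adj": "JJ",
    "adv": "AD",
    "pron": "PN",
    "num": "CD",
    "punct": "PU",
}

# Relative frequency of background classes in template slots.
_CLASS_WEIGHTS = {
    "noun": 0.34,
    "verb": 0.20,
    "adj": 0.14,
    "adv": 0.10,
    "pron": 0.08,
    "num": 0.07,
    "punct": 0.07,
}

# Mention frequency by type; disease_group is deliberately rare — it is
# the hardest class in the real evaluation tables.
_ENTITY_WEIGHTS = {
    "disease": 0.28,
    "symptom": 0.27,
    "treatment": 0.20,
    "test": 0.23,
    "disease_group": 0.02,
}

# Per-type word suffixes: entity surface forms share morphology within a
# type, so character-level features generalise across domains.
_TYPE_SUFFIXES = {
    "disease": ("itis", "osis", "oma"),
    "symptom": ("algia", "pnea", "emia"),
    "treatment": ("mycin", "olol", "pril"),
    "test": ("scan", "gram", "assay"),
    "disease_group": ("opathy", "oses"),
}

_CLASS_SUFFIXES = {
    "noun": ("a", "us", "um"),
    "verb": ("ate", "ize", "ify"),
    "adj": ("ic", "ous", "al"),
    "adv": ("ly",),
    "pron": ("he", "it", "we"),
}

_CONSONANTS = "bcdfghjklmnpqrstvz"
_VOWELS = "aeiou"


@dataclass
class DomainSpec:
    """Lexical resources for one domain."""

    entity_lexicons: dict[str, list[tuple[str, ...]]]
    background_lexicon: dict[str, list[str]]  # class -> words
    sentence_templates: list[tuple[str, ...]]
    mention_length_distribution: dict[int, float]

    def __post_init__(self) -> None:
        for etype, phrases in self.entity_lexicons.items():
            if not phrases:
                raise ValueError(f"entity type {etype!r} has an empty lexicon")
        total = sum(self.mention_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mention length distribution must sum to 1")
        known = set(POS_CLASSES) | {"ENT"}
        for tpl in self.sentence_templates:
            for slot in tpl:
                if slot not in known:
                    raise ValueError(f"template slot {slot!r} is not a known class")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic two-domain pair.

    Defaults mirror the intended workload: a general-domain corpus an
    order of magnitude larger than the target, ~2,000 background words,
    ~40 entity phrases per type, sentences of 5–25 tokens, and a 0.7
    vocabulary overlap between the domains.
    """

    seed: int = 0
    n_sentences_general: int = 5000
    n_sentences_target: int = 500
    vocabulary_overlap: float = 0.7
    label_noise_rate: float = 0.0
    n_background_words: int = 2000
    phrases_per_type: int = 40
    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES
    mention_length_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    )
    n_templates: int = 40

    def __post_init__(self) -> None:
        if self.n_sentences_general < 0 or self.n_sentences_target < 0:
            raise ValueError("sentence counts must be ≥ 0")
        if not 0.0 <= self.vocabulary_overlap <= 1.0:
            raise ValueError("vocabulary_overlap must be in [0, 1]")
        if not 0.0 <= self.label_noise_rate <= 1.0:
            raise ValueError("label_noise_rate must be in [0, 1]")


def _new_word(rng: np.random.Generator, suffix: str, used: set[str]) -> str:
    """A fresh syllable word ending in ``suffix``; unique across the run."""
    for _ in range(1000):
        n_syll = int(rng.integers(2, 4))
        stem = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        word = stem + suffix
        if word not in used:
            used.add(word)
            return word
    raise RuntimeError("word pool exhausted")


def _split_pool(
    pool: list, overlap: float, rng: np.random.Generator
) -> tuple[list, list]:
    """Split a pool into (general, target) lists sharing ``overlap``.

    Both lists have the same size as the fraction-adjusted pool; with
    overlap 1.0 they are identical, so the target vocabulary is a subset
    of the general one.
    """
    n = len(pool)
    n_shared = int(round(overlap * n))
    if n_shared == 0 and overlap > 0 and n > 0:
        n_shared = 1
    shared = pool[:n_shared]
    rest = pool[n_shared:]
    half = len(rest) // 2
    general = shared + rest[:half]
    target = shared + rest[half:]
    if not general or not target:
        raise ValueError("zero-size lexicon after overlap split")
    return general, target


def _make_phrase(
    rng: np.random.Generator,
    etype: str,
    length: int,
    used: set[str],
) -> tuple[str, ...]:
    # Head word carries the type suffix; modifiers are plain adjectives,
    # so multi-token mentions look like "ravic tubitis".
    suffixes = _TYPE_SUFFIXES[etype]
    head = _new_word(rng, suffixes[rng.integers(len(suffixes))], used)
    mods = tuple(
        _new_word(rng, _CLASS_SUFFIXES["adj"][rng.integers(3)], used)
        for _ in range(length - 1)
    )
    return mods + (head,)


def build_domain_pair_specs(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[DomainSpec, DomainSpec]:
    """Build (general, target) DomainSpecs sharing lexicon per the overlap."""
    used: set[str] = set()
    lengths = sorted(config.mention_length_distribution)
    probs = np.array([config.mention_length_distribution[k] for k in lengths])

    gen_entities: dict[str, list[tuple[str, ...]]] = {}
    tgt_entities: dict[str, list[tuple[str, ...]]] = {}
    for etype in config.entity_types:
        # Guarantee every length is represented so length-conditional
        # sampling is always possible, then fill the rest at random.
        pool: list[tuple[str, ...]] = [
            _make_phrase(rng, etype, ln, used) for ln in lengths
        ]
        # Pool is oversized so each domain keeps phrases_per_type phrases.
        n_pool = max(config.phrases_per_type + len(lengths), 2 * len(lengths))
        while len(pool) < n_pool:
            ln = lengths[rng.choice(len(lengths), p=probs)]
            pool.append(_make_phrase(rng, etype, ln, used))
        g, t = _split_pool(pool, config.vocabulary_overlap, rng)
        for dom_list in (g, t):
            have = {len(p) for p in dom_list}
            for ln in lengths:
                if ln not in have:
                    dom_list.append(_make_phrase(rng, etype, ln, used))
        gen_entities[etype] = g
        tgt_entities[etype] = t

    gen_background: dict[str, list[str]] = {}
    tgt_background: dict[str, list[str]] = {}
    n_classes = len(_CLASS_WEIGHTS)
    for cls, weight in _CLASS_WEIGHTS.items():
        if cls == "punct":
            words = [",", ".", ";", ":"]
            gen_background[cls] = words
            tgt_background[cls] = list(words)
            continue
        n_words = max(4, int(round(config.n_background_words * weight)))
        if cls == "num":
            pool = [str(int(v)) for v in rng.integers(1, 10**4, size=n_words)]
            pool = list(dict.fromkeys(pool))
        else:
            suffixes = _CLASS_SUFFIXES[cls]
            pool = [
                _new_word(rng, suffixes[rng.integers(len(suffixes))], used)
                for _ in range(n_words)
            ]
        gen_background[cls], tgt_background[cls] = _split_pool(
            pool, config.vocabulary_overlap, rng
        )
    del n_classes

    # Templates are shared between the domains: the domains differ in
    # vocabulary, not in syntax.
    classes = [c for c in _CLASS_WEIGHTS]
    cls_probs = np.array([_CLASS_WEIGHTS[c] for c in classes])
    cls_probs = cls_probs / cls_probs.sum()
    templates: list[tuple[str, ...]] = []
    while len(templates) < config.n_templates:
        n_slots = int(rng.integers(5, 19))
        slots = []
        for _ in range(n_slots):
            if rng.random() < 0.16:
                slots.append("ENT")
            else:
                slots.append(classes[rng.choice(len(classes), p=cls_probs)])
        templates.append(tuple(slots))
    # At least one entity-free template keeps all-O sentences in the mix.
    templates[0] = tuple(
        classes[rng.choice(len(classes), p=cls_probs)] for _ in range(7)
    )

    mld = dict(config.mention_length_distribution)
    general = DomainSpec(gen_entities, gen_background, templates, mld)
    target = DomainSpec(tgt_entities, tgt_background, templates, mld)
    return general, target


def _sample_sentence(
    spec: DomainSpec,
    config: GeneratorConfig,
    rng: np.random.Generator,
    etypes: list[str],
    etype_probs: np.ndarray,
) -> Sentence:
    lengths = sorted(spec.mention_length_distribution)
    len_probs = np.array([spec.mention_length_distribution[k] for k in lengths])
    tpl = spec.sentence_templates[rng.integers(len(spec.sentence_templates))]
    tokens: list[Token] = []
    for slot in tpl:
        if slot == "ENT":
            etype = etypes[rng.choice(len(etypes), p=etype_probs)]
            # Length-conditional draw keeps the empirical mention-length
            # distribution tied to the configured one.
            ln = lengths[rng.choice(len(lengths), p=len_probs)]
            candidates = [p for p in spec.entity_lexicons[etype] if len(p) == ln]
            phrase = candidates[rng.integers(len(candidates))]
            for j, word in enumerate(phrase):
                tag = ("B-" if j == 0 else "I-") + etype
                tokens.append(Token(word, POS_CLASSES["noun"], tag))
        else:
            words = spec.background_lexicon[slot]
            word = words[rng.integers(len(words))]
            tokens.append(Token(word, POS_CLASSES[slot], "O"))
    return Sentence(tuple(tokens))


def _generate_corpus(
    spec: DomainSpec,
    config: GeneratorConfig,
    n_sentences: int,
    rng: np.random.Generator,
    domain_name: str,
) -> Corpus:
    etypes = list(config.entity_types)
    probs = np.array([_ENTITY_WEIGHTS.get(t, 0.1) for t in etypes])
    probs = probs / probs.sum()
    sentences = [
        _sample_sentence(spec, config, rng, etypes, probs) for _ in range(n_sentences)
    ]
    return Corpus(sentences, domain_name=domain_name)


def generate_domain_pair(config: GeneratorConfig) -> tuple[Corpus, Corpus]:
    """Generate the (general, target) corpus pair.

    One RNG stream per corpus (plus one for the shared lexicons) is
    derived from the master seed, so regenerating either corpus alone is
    reproducible.  Identical seeds give identical corpora.
    """
    ss = np.random.SeedSequence(config.seed)
    lex_seed, gen_seed, tgt_seed, noise_seed = ss.spawn(4)
    spec_general, spec_target = build_domain_pair_specs(
        config, np.random.default_rng(lex_seed)
    )
    general = _generate_corpus(
        spec_general,
        config,
        config.n_sentences_general,
        np.random.default_rng(gen_seed),
        "general",
    )
    target = _generate_corpus(
        spec_target,
        config,
        config.n_sentences_target,
        np.random.default_rng(tgt_seed),
        "target",
    )
    if config.label_noise_rate > 0:
        target = perturb_labels(
            target,
            config.label_noise_rate,
            int(noise_seed.generate_state(1)[0] % (2**31)),
        )
    return general, target


def perturb_labels(corpus: Corpus, rate: float, seed: int) -> Corpus:
    """Delete each entity mention (tags → O) independently with ``rate``.

    Returns a new corpus; the input is untouched.  Supports robustness
    experiments with partially-annotated gold data.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sentences: list[Sentence] = []
    for sent in corpus:
        mentions = decode_entities(sent.ner_tags)
        kept = [m for m in mentions if rng.random() >= rate]
        tags = mentions_to_bio(kept, len(sent))
        sentences.append(
            Sentence(
                tuple(
                    Token(t.surface, t.pos, tag)
                    for t, tag in zip(sent.tokens, tags)
                )
            )
        )
    return Corpus(sentences, domain_name=corpus.domain_name)
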