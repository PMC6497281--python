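"""Token- and entity-level scoring for sequence tagging.

Three families of scores are reported, mirroring the standard clinical
NER evaluation protocol:

* **micro** precision/recall/F — confusion counts pooled over *all*
  token label classes, including ``O``.  Under single-label-per-token
  prediction this pooling forces micro P = R = F (all three equal token
  accuracy), which is why comparison tables show one repeated value.
* **per-type / macro** precision/recall/F — exact-match span scoring per
  entity type (a predicted mention counts only if an identical
  (type, sentence, span) mention exists in gold), macro = unweighted
  mean over the types present.
* **entity accuracy** — the fraction of *gold* mentions reproduced
  exactly in the prediction, per type and overall.  By construction it
  is a recall-style rate: spurious predictions do not lower it.

All scores are percentages in [0, 100].  Rounding (half-up, 2 decimals)
happens only at rendering time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from medtagger.corpus import Corpus, EntityMention


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    # Precision with an empty prediction set is defined as 0 (flagged in
    # the report rather than raising).
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    # F computed from the raw counts: algebraically the harmonic mean of
    # P and R, and bitwise equal to both whenever FP == FN (the micro
    # identity under all-class single-label aggregation).
    f = 200.0 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return p, r, f


def token_micro_metrics(
    gold: Sequence[Sequence[str]],
    pred: Sequence[Sequence[str]],
    include_o: bool = True,
) -> tuple[float, float, float]:
    """Micro-averaged token precision/recall/F over all label classes.

    ``gold`` and ``pred`` are parallel per-sentence label sequences.
    With ``include_o`` (the default) the ``O`` class participates in the
    pooled counts; since every token receives exactly one label, pooled
    FP equals pooled FN and micro P = R = F = token accuracy.
    """
    if len(gold) != len(pred):
        raise ValueError("gold and pred have different sentence counts")
    tp: Counter[str] = Counter()
    fp: Counter[str] = Counter()
    fn: Counter[str] = Counter()
    for gseq, pseq in zip(gold, pred):
        if len(gseq) != len(pseq):
            raise ValueError("gold and pred sentence lengths differ")
        for g, p in zip(gseq, pseq):
            if g == p:
                tp[g] += 1
            else:
                fp[p] += 1
                fn[g] += 1
    classes = set(tp) | set(fp) | set(fn)
    if not include_o:
        classes.discard("O")
    t = sum(tp[c] for c in classes)
    f_pos = sum(fp[c] for c in classes)
    f_neg = sum(fn[c] for c in classes)
    return _prf(t, f_pos, f_neg)


def entity_type_metrics(
    gold_mentions: Iterable[EntityMention],
    pred_mentions: Iterable[EntityMention],
) -> dict[str, tuple[float, float, float]]:
    """Exact-match span precision/recall/F per entity type.

    A predicted mention is a true positive iff gold contains a mention
    with the same type, sentence index and token span.  Types absent
    from both lists do not appear in the result (and are therefore
    excluded from the macro average).
    """
    gold_set = set(gold_mentions)
    pred_set = set(pred_mentions)
    types = sorted(
        {m.entity_type for m in gold_set} | {m.entity_type for m in pred_set}
    )
    out: dict[str, tuple[float, float, float]] = {}
    for t in types:
        g = {m for m in gold_set if m.entity_type == t}
        p = {m for m in pred_set if m.entity_type == t}
        tp = len(g & p)
        out[t] = _prf(tp, len(p) - tp, len(g) - tp)
    return out


def macro_average(
    per_type: Mapping[str, tuple[float, float, float]],
) -> tuple[float, float, float]:
    """Unweighted arithmetic mean of per-type precision, recall and F."""
    if not per_type:
        raise ValueError("macro average needs at least one type")
    n = len(per_type)
    p = sum(v[0] for v in per_type.values()) / n
    r = sum(v[1] for v in per_type.values()) / n
    f = sum(v[2] for v in per_type.values()) / n
    return p, r, f


def entity_accuracy(
    gold_mentions: Iterable[EntityMention],
    pred_mentions: Iterable[EntityMention],
) -> tuple[dict[str, float | None], float]:
    """Exact-match rate over gold mentions, per type and overall.

    Per type: exactly-matched gold mentions ÷ gold mentions of that
    type, × 100; ``None`` when the type has no gold mentions (rendered
    as N/A).  Overall: matched ÷ all gold mentions.  Extra predicted
    mentions never lower these rates.
    """
    gold_set = set(gold_mentions)
    pred_set = set(pred_mentions)
    matched = gold_set & pred_set
    types = sorted(
        {m.entity_type for m in gold_set} | {m.entity_type for m in pred_set}
    )
    per_type: dict[str, float | None] = {}
    for t in types:
        n_gold = sum(1 for m in gold_set if m.entity_type == t)
        n_hit = sum(1 for m in matched if m.entity_type == t)
        per_type[t] = 100.0 * n_hit / n_gold if n_gold else None
    overall = 100.0 * len(matched) / len(gold_set) if gold_set else 0.0
    return per_type, overall


@dataclass
class MetricsReport:
    """Full score card for one gold/prediction pair."""

    micro_p: float
    micro_r: float
    micro_f: float
    per_type: dict[str, tuple[float, float, float]]
    macro_p: float
    macro_r: float
    macro_f: float
    per_type_accuracy: dict[str, float | None]
    overall_accuracy: float
    n_sentences: int = 0
    n_tokens: int = 0
    n_gold_mentions: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "micro_p": self.micro_p,
            "micro_r": self.micro_r,
            "micro_f": self.micro_f,
            "per_type": {k: list(v) for k, v in self.per_type.items()},
            "macro_p": self.macro_p,
            "macro_r": self.macro_r,
            "macro_f": self.macro_f,
            "per_type_accuracy": dict(self.per_type_accuracy),
            "overall_accuracy": self.overall_accuracy,
            "n_sentences": self.n_sentences,
            "n_tokens": self.n_tokens,
            "n_gold_mentions": self.n_gold_mentions,
        }


def evaluate_sequences(
    gold: Sequence[Sequence[str]],
    pred: Sequence[Sequence[str]],
    include_o: bool = True,
) -> MetricsReport:
    """Score predicted BIO sequences against gold ones."""
    from medtagger.corpus import decode_entities

    micro = token_micro_metrics(gold, pred, include_o=include_o)
    gold_mentions = [
        m for i, seq in enumerate(gold) for m in decode_entities(seq, i)
    ]
    pred_mentions = [
        m for i, seq in enumerate(pred) for m in decode_entities(seq, i)
    ]
    per_type = entity_type_metrics(gold_mentions, pred_mentions)
    macro = macro_average(per_type) if per_type else (0.0, 0.0, 0.0)
    per_acc, overall = entity_accuracy(gold_mentions, pred_mentions)
    return MetricsReport(
        micro_p=micro[0],
        micro_r=micro[1],
        micro_f=micro[2],
        per_type=per_type,
        macro_p=macro[0],
        macro_r=macro[1],
        macro_f=macro[2],
        per_type_accuracy=per_acc,
        overall_accuracy=overall,
        n_sentences=len(gold),
        n_tokens=sum(len(s) for s in gold),
        n_gold_mentions=len(gold_mentions),
    )


def evaluate_corpora(gold: Corpus, pred: Corpus, include_o: bool = True) -> MetricsReport:
    """Score a predicted corpus against gold (same sentences, same order)."""
    if len(gold) != len(pred):
        raise ValueError(
            f"sentence-count mismatch: gold {len(gold)}, predicted {len(pred)}"
        )
    return evaluate_sequences(
        gold.ner_sequences(), pred.ner_sequences(), include_o=include_o
    )


def _fmt(value: float | None, width: int = 10) -> str:
    if value is None:
        return "N/A".rjust(width)
    return f"{round_half_up(value):.2f}".rjust(width)


def render_report(report: MetricsReport, style: str = "per-type-table") -> str:
    """Render one of the three table styles as fixed-width text.

    Styles: ``micro-table`` (pooled P/R/F), ``per-type-table`` (per-type
    and macro P/R/F) and ``accuracy-table`` (exact-match rates).
    Percentages are printed with 2 decimals, half-up; missing cells as
    ``N/A``.  Output is deterministic.
    """
    lines: list[str] = []
    if style == "micro-table":
        lines.append(f"{'':<16}{'MicroP':>10}{'MicroR':>10}{'MicroF':>10}")
        lines.append(
            f"{'all classes':<16}"
            f"{_fmt(report.micro_p)}{_fmt(report.micro_r)}{_fmt(report.micro_f)}"
        )
    elif style == "per-type-table":
        lines.append(
            f"{'Entity type':<16}{'Precision':>10}{'Recall':>10}{'F-measure':>10}"
        )
        for etype in sorted(report.per_type):
            p, r, f = report.per_type[etype]
            lines.append(f"{etype:<16}{_fmt(p)}{_fmt(r)}{_fmt(f)}")
        lines.append(
            f"{'Macro average':<16}"
            f"{_fmt(report.macro_p)}{_fmt(report.macro_r)}{_fmt(report.macro_f)}"
        )
    elif style == "accuracy-table":
        lines.append(f"{'Entity type':<16}{'Accuracy':>10}")
        for etype in sorted(report.per_type_accuracy):
            lines.append(f"{etype:<16}{_fmt(report.per_type_accuracy[etype])}")
        lines.append(f"{'Overall':<16}{_fmt(report.overall_accuracy)}")
    else:
        raise ValueError(f"unknown table style {style!r}")
    return "\n".join(lines) + "\n"
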