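"""Event scoring with approximate-span and recursive-argument matching.

``approximate`` counts a predicted event as correct when its label and
negation flag agree with a gold event, the trigger spans overlap, and
every argument role matches recursively (entity arguments by span
overlap, event arguments by recursive equivalence).  ``strict``
requires exact spans throughout.  Matching between prediction and gold
sets is a maximum bipartite matching, so double-crediting is
impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from litnet.entities import EntityMention
from litnet.events import EventMention


@dataclass
class ScoreReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_label: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def precision(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        if self.tp + self.fn == 0:
            return None
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return 0.0 if (p == 0 or r == 0) else None
        return 2 * p * r / (p + r)


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _mentions_match(p: EntityMention, g: EntityMention, mode: str) -> bool:
    if p.sent_index != g.sent_index:
        return False
    if mode == "strict":
        return p.span == g.span
    return _spans_overlap(p.span, g.span)


def events_match(pred: EventMention, gold: EventMention, mode: str = "approximate") -> bool:
    if pred.label != gold.label or pred.negated != gold.negated:
        return False
    if pred.sent_index != gold.sent_index:
        return False
    if mode == "strict":
        if pred.trigger != gold.trigger:
            return False
    elif not _spans_overlap(pred.trigger, gold.trigger):
        return False
    if set(pred.arguments) != set(gold.arguments):
        return False
    for role in gold.arguments:
        if not _arg_lists_match(pred.arguments[role], gold.arguments[role], mode):
            return False
    return True


def _arg_lists_match(pred: list, gold: list, mode: str) -> bool:
    if len(pred) != len(gold):
        return False
    return _bipartite_match_count(pred, gold, lambda p, g: _arg_match(p, g, mode)) == len(gold)


def _arg_match(p, g, mode: str) -> bool:
    if isinstance(p, EntityMention) and isinstance(g, EntityMention):
        return _mentions_match(p, g, mode)
    if isinstance(p, EventMention) and isinstance(g, EventMention):
        return events_match(p, g, mode)
    return False


def _bipartite_match_count(left: Sequence, right: Sequence, ok) -> int:
    """Maximum bipartite matching by augmenting paths (small inputs)."""
    match_r: dict[int, int] = {}

    def try_assign(li: int, seen: set[int]) -> bool:
        for ri in range(len(right)):
            if ri in seen or not ok(left[li], right[ri]):
                continue
            seen.add(ri)
            if ri not in match_r or try_assign(match_r[ri], seen):
                match_r[ri] = li
                return True
        return False

    count = 0
    for li in range(len(left)):
        if try_assign(li, set()):
            count += 1
    return count


def score(
    predicted: Sequence[EventMention],
    gold: Sequence[EventMention],
    mode: str = "approximate",
) -> ScoreReport:
    """Score predicted events against gold for one document set.

    Raises ``ValueError`` when the two sides reference different
    document ids.
    """
    if mode not in ("approximate", "strict"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    pred_docs = {e.doc_id for e in predicted}
    gold_docs = {e.doc_id for e in gold}
    if predicted and gold and pred_docs - gold_docs and gold_docs - pred_docs:
        raise ValueError(
            f"document id mismatch: predictions {sorted(pred_docs)} vs gold {sorted(gold_docs)}"
        )
    report = ScoreReport()
    labels = sorted({e.label for e in list(predicted) + list(gold)})
    for label in labels:
        p = [e for e in predicted if e.label == label]
        g = [e for e in gold if e.label == label]
        by_doc = sorted({e.doc_id for e in p + g})
        tp = 0
        for doc in by_doc:
            pd = [e for e in p if e.doc_id == doc]
            gd = [e for e in g if e.doc_id == doc]
            tp += _bipartite_match_count(pd, gd, lambda a, b: events_match(a, b, mode))
        fp = len(p) - tp
        fn = len(g) - tp
        report.tp += tp
        report.fp += fp
        report.fn += fn
        report.per_label[label] = (tp, fp, fn)
    return report
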