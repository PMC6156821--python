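"""Sign correction for nested events via polarity-reversal words.

The dependency path connecting a nested event's trigger to each of its
in-sentence arguments is scanned for reversal words; adjectival
modifiers hanging off any path node are scanned too.  The final sign is
the trigger's base sign flipped once per cue (parity semantics), so
"decreased X expression enhances Y phosphorylation" comes out negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from litnet.entities import EntityMention
from litnet.events import (
    ACTIVATION_LABELS,
    REGULATION_LABELS,
    EventMention,
)
from litnet.preprocess import ROOT, Sentence

DEFAULT_REVERSAL_FORMS = frozenset(
    {
        "decreased", "decrease", "reduced", "reduction", "diminished",
        "loss", "lack", "absence", "depletion", "deficiency", "knockdown",
        "silencing", "inhibition", "suppression", "ablation", "impaired",
        "lowered", "disruption", "downregulation",
    }
)


@dataclass(frozen=True)
class PolarityLexicon:
    """Lower-cased reversal forms, optionally POS-constrained."""

    forms: frozenset[str] = DEFAULT_REVERSAL_FORMS
    pos_prefixes: tuple[str, ...] = ()  # empty = any POS

    def __post_init__(self) -> None:
        if not self.forms:
            raise ValueError("polarity lexicon must be non-empty")
        object.__setattr__(self, "forms", frozenset(f.lower() for f in self.forms))

    def matches(self, text: str, lemma: str, pos: str) -> bool:
        if self.pos_prefixes and not any(pos.startswith(p) for p in self.pos_prefixes):
            return False
        return text.lower() in self.forms or lemma.lower() in self.forms


def load_polarity_lexicon(rows: Iterable[str]) -> PolarityLexicon:
    """Load a TSV of (form, POS prefix, weight) rows; weight is ignored
    beyond checking it encodes a reversal (-1)."""
    forms = set()
    for line in rows:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        forms.add(cols[0].lower())
    return PolarityLexicon(forms=frozenset(forms))


def _heads(sentence: Sentence) -> dict[int, int]:
    return {e.dependent: e.head for e in sentence.deps}


def _path_nodes(sentence: Sentence, a: int, b: int) -> list[int]:
    """Nodes on the unique tree path between tokens a and b (inclusive)."""
    heads = _heads(sentence)

    def ancestors(x: int) -> list[int]:
        out = [x]
        while heads.get(x, ROOT) != ROOT:
            x = heads[x]
            out.append(x)
        return out

    up_a = ancestors(a)
    up_b = ancestors(b)
    set_a = set(up_a)
    lca = next((x for x in up_b if x in set_a), None)
    if lca is None:
        return []
    path = up_a[: up_a.index(lca) + 1]
    path += list(reversed(up_b[: up_b.index(lca)]))
    return path


def _argument_anchor(arg) -> int | None:
    if isinstance(arg, EntityMention):
        return arg.end - 1
    if isinstance(arg, EventMention):
        return arg.trigger[0]
    return None


def collect_reversal_cues(
    event: EventMention,
    sentence: Sentence,
    lexicon: PolarityLexicon | None = None,
) -> list[int]:
    """Reversal-cue tokens on the trigger-argument paths.

    Cues are path nodes themselves plus ``amod`` dependents attached
    anywhere along a path; material inside an argument's own subtree is
    out of scope.  Returns token indices, deduplicated, in text order.
    """
    lexicon = lexicon or PolarityLexicon()
    if not sentence.deps:
        return []
    trig = event.trigger[0]
    nodes: set[int] = set()
    for arg in event.participants():
        if isinstance(arg, EventMention) and arg.sent_index != event.sent_index:
            continue
        anchor = _argument_anchor(arg)
        if anchor is None:
            continue
        nodes.update(_path_nodes(sentence, trig, anchor))
    nodes.discard(trig)
    candidates = set(nodes)
    for n in set(nodes) | {trig}:
        for d, lbl in sentence.children(n):
            if lbl == "amod":
                candidates.add(d)
    cues = []
    for n in sorted(candidates):
        t = sentence.tokens[n]
        if lexicon.matches(t.text, t.lemma, t.pos):
            cues.append(n)
    return cues


def correct_polarity(event: EventMention, cues: Sequence[int]) -> EventMention:
    """Flip the event's sign once per cue (in place); simple events are
    returned unchanged."""
    if not event.is_nested():
        return event
    sign = event.sign * (-1) ** len(cues)
    event.sign = sign
    table = (
        REGULATION_LABELS
        if event.label in REGULATION_LABELS.values()
        else ACTIVATION_LABELS
    )
    event.label = table[sign]
    return event


def apply_polarity(
    events: Iterable[EventMention],
    sentence: Sentence,
    lexicon: PolarityLexicon | None = None,
) -> None:
    """Correct every nested event of one sentence in place."""
    for ev in events:
        if ev.is_nested():
            correct_polarity(ev, collect_reversal_cues(ev, sentence, lexicon))
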