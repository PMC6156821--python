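"""Sieve-based coreference for entity and event anaphors.

Deterministic sieves run in precision order; the first sieve to resolve
an anaphor wins.  Resolved anaphors are substituted back into their
sentences and event extraction is re-run there, so events whose
arguments were pronominal or definite references ("this protein",
"the K134A mutant", "this binding") can be recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

from litnet.entities import EntityMention, MUTANT_VARIANT_RE
from litnet.events import EventMention
from litnet.preprocess import Document

log = logging.getLogger(__name__)

#: how many sentences back an antecedent may live (plus the current one)
DEFAULT_WINDOW = 2

#: generic event-anaphor head nouns -> compatible event labels
EVENT_ANAPHOR_NOUNS: dict[str, frozenset[str]] = {
    "interaction": frozenset({"binding"}),
    "binding": frozenset({"binding"}),
    "complex": frozenset({"binding"}),
    "association": frozenset({"binding"}),
    "modification": frozenset(
        {"phosphorylation", "ubiquitination", "hydroxylation", "sumoylation",
         "glycosylation", "acetylation", "farnesylation", "ribosylation",
         "methylation"}
    ),
}

_DEMONSTRATIVES = {"this", "that", "these", "those", "the"}


@dataclass
class Anaphor:
    sent_index: int
    start: int  # token span, half-open
    end: int
    text: str
    kind: str  # "entity" | "mutant" | "event"
    entity_type: str | None = None
    labels: frozenset[str] = frozenset()
    variant: str | None = None
    plural: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CorefLink:
    anaphor: Anaphor
    antecedent: object  # EntityMention | EventMention
    sieve: str
    rank: int

    def __post_init__(self) -> None:
        ant_sent = (
            self.antecedent.sent_index
            if isinstance(self.antecedent, (EntityMention, EventMention))
            else -1
        )
        ant_pos = getattr(self.antecedent, "start", None)
        if ant_pos is None:
            ant_pos = self.antecedent.trigger[0]
        if (ant_sent, ant_pos) >= (self.anaphor.sent_index, self.anaphor.start):
            raise ValueError("antecedent must precede its anaphor")


# ---------------------------------------------------------------------
# anaphor detection
# ---------------------------------------------------------------------


def find_anaphors(
    document: Document,
    mentions: Sequence[EntityMention],
    events: Sequence[EventMention],
) -> list[Anaphor]:
    """Definite/demonstrative NPs referring back to entities or events."""
    out: list[Anaphor] = []
    for si, sent in enumerate(document.sentences):
        toks = sent.tokens
        for i, tok in enumerate(toks):
            low = tok.text.lower()
            if low not in _DEMONSTRATIVES or i + 1 >= len(toks):
                continue
            nxt = toks[i + 1].text
            nxt_low = nxt.lower()
            # "the K134A mutant"
            if (
                MUTANT_VARIANT_RE.match(nxt)
                and i + 2 < len(toks)
                and toks[i + 2].text.lower() in ("mutant", "mutants")
            ):
                out.append(
                    Anaphor(
                        sent_index=si, start=i + 1, end=i + 3,
                        text=sent.span_text(i + 1, i + 3),
                        kind="mutant", variant=nxt,
                    )
                )
                continue
            # "this interaction" / "this binding"
            if nxt_low in EVENT_ANAPHOR_NOUNS and low in ("this", "that", "the"):
                out.append(
                    Anaphor(
                        sent_index=si, start=i + 1, end=i + 2,
                        text=nxt,
                        kind="event", labels=EVENT_ANAPHOR_NOUNS[nxt_low],
                    )
                )
                continue
        # generic entity NPs come from the generic-entity grammar rules
        for m in mentions:
            if m.sent_index == si and m.generic:
                head = sent.tokens[m.end - 1].text
                out.append(
                    Anaphor(
                        sent_index=si, start=m.end - 1, end=m.end,
                        text=head,
                        kind="entity", entity_type=m.entity_type,
                        plural=head.lower().endswith("s"),
                    )
                )
    out.sort(key=lambda a: (a.sent_index, a.start))
    # dedupe overlapping detections, preferring the more specific kinds
    pref = {"mutant": 0, "event": 1, "entity": 2}
    chosen: list[Anaphor] = []
    for a in sorted(out, key=lambda a: (a.sent_index, a.start, pref[a.kind])):
        if any(
            c.sent_index == a.sent_index and not (a.end <= c.start or a.start >= c.end)
            for c in chosen
        ):
            continue
        chosen.append(a)
    return sorted(chosen, key=lambda a: (a.sent_index, a.start))


# ---------------------------------------------------------------------
# sieves
# ---------------------------------------------------------------------

Sieve = Callable[[Anaphor, Sequence[EntityMention], Sequence[EventMention], int], object]


def _window_mentions(
    anaphor: Anaphor, mentions: Sequence[EntityMention], window: int
) -> list[EntityMention]:
    lo = anaphor.sent_index - window
    out = []
    for m in mentions:
        if m.generic:
            continue
        if lo <= m.sent_index < anaphor.sent_index or (
            m.sent_index == anaphor.sent_index and m.end <= anaphor.start
        ):
            out.append(m)
    return sorted(out, key=lambda m: (m.sent_index, m.start))


def _window_events(
    anaphor: Anaphor, events: Sequence[EventMention], window: int
) -> list[EventMention]:
    lo = anaphor.sent_index - window
    out = []
    for e in events:
        if lo <= e.sent_index < anaphor.sent_index or (
            e.sent_index == anaphor.sent_index and e.trigger[1] <= anaphor.start
        ):
            out.append(e)
    return sorted(out, key=lambda e: (e.sent_index, e.trigger[0]))


def sieve_exact_match(anaphor, mentions, events, window):
    """Highest precision: the anaphor repeats an earlier mention's text."""
    for m in reversed(_window_mentions(anaphor, mentions, window)):
        if m.text.casefold() == anaphor.text.casefold():
            return m
    return None


def sieve_mutant_alias(anaphor, mentions, events, window):
    """'the K134A mutant' links to an entity carrying Mutant(K134A)."""
    if anaphor.kind != "mutant" or not anaphor.variant:
        return None
    for m in reversed(_window_mentions(anaphor, mentions, window)):
        for mod in m.modifications:
            if mod.kind == "Mutant" and mod.variant == anaphor.variant:
                return m
    return None


def sieve_event_label(anaphor, mentions, events, window):
    """Event anaphor links to the most recent label-compatible event."""
    if anaphor.kind != "event":
        return None
    for e in reversed(_window_events(anaphor, events, window)):
        if e.label in anaphor.labels:
            return e
    return None


def sieve_nearest_type(anaphor, mentions, events, window):
    """Lowest precision: nearest preceding type-compatible entity."""
    if anaphor.kind != "entity":
        return None
    if anaphor.plural:
        return None  # no coordinated-antecedent support
    for m in reversed(_window_mentions(anaphor, mentions, window)):
        if anaphor.entity_type is None or m.entity_type == anaphor.entity_type:
            return m
    return None


DEFAULT_SIEVES: tuple[tuple[str, Sieve], ...] = (
    ("exact_match", sieve_exact_match),
    ("mutant_alias", sieve_mutant_alias),
    ("event_label", sieve_event_label),
    ("nearest_type", sieve_nearest_type),
)


def apply_sieves(
    document: Document,
    anaphors: Sequence[Anaphor],
    mentions: Sequence[EntityMention],
    events: Sequence[EventMention],
    sieves: Sequence[tuple[str, Sieve]] = DEFAULT_SIEVES,
    window: int = DEFAULT_WINDOW,
) -> list[CorefLink]:
    """Run the sieve cascade; first resolving sieve wins per anaphor."""
    links: list[CorefLink] = []
    for anaphor in anaphors:
        for rank, (name, sieve) in enumerate(sieves):
            antecedent = sieve(anaphor, mentions, events, window)
            if antecedent is not None:
                links.append(CorefLink(anaphor, antecedent, name, rank))
                break
        else:
            log.info(
                "unresolved anaphor %r at sentence %d", anaphor.text, anaphor.sent_index
            )
    return links


# ---------------------------------------------------------------------
# substitution for re-extraction
# ---------------------------------------------------------------------


def alias_mention(link: CorefLink, doc_id: str) -> EntityMention | None:
    """An entity mention standing in for a resolved entity anaphor."""
    ant = link.antecedent
    if not isinstance(ant, EntityMention):
        return None
    return EntityMention(
        doc_id=doc_id,
        sent_index=link.anaphor.sent_index,
        start=link.anaphor.start,
        end=link.anaphor.end,
        text=ant.text,
        entity_type=ant.entity_type,
        groundings=list(ant.groundings),
        modifications=list(ant.modifications),
        generic=False,
    )


def alias_event(link: CorefLink) -> EventMention | None:
    """A copy of a resolved event antecedent anchored at the anaphor span,
    so dependency paths landing on the anaphor bind the antecedent's
    content."""
    ant = link.antecedent
    if not isinstance(ant, EventMention):
        return None
    return EventMention(
        doc_id=ant.doc_id,
        sent_index=link.anaphor.sent_index,
        label=ant.label,
        trigger=link.anaphor.span,
        trigger_text=link.anaphor.text,
        arguments={k: list(v) for k, v in ant.arguments.items()},
        sign=ant.sign,
        negated=ant.negated,
        rule=ant.rule,
        coref=True,
    )
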