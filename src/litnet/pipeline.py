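"""End-to-end extraction: entities -> events -> polarity -> coref."""

from __future__ import annotations

from dataclasses import dataclass, field

from litnet.coref import (
    CorefLink,
    alias_event,
    alias_mention,
    apply_sieves,
    find_anaphors,
)
from litnet.entities import KB, EntityMention, attach_states, ground, match_entities
from litnet.events import (
    EventMention,
    apply_negation,
    extract_nested_events,
    extract_simple_events,
)
from litnet.grammar import Grammar, load_default_grammar
from litnet.polarity import PolarityLexicon, apply_polarity
from litnet.preprocess import Document


@dataclass
class ExtractionResult:
    doc_id: str
    mentions: list[EntityMention] = field(default_factory=list)
    events: list[EventMention] = field(default_factory=list)
    links: list[CorefLink] = field(default_factory=list)


def extract_sentence_events(
    sentence,
    mentions,
    grammar: Grammar,
    doc_id: str,
    sent_index: int,
    extra_events: list[EventMention] | None = None,
    polarity_lexicon: PolarityLexicon | None = None,
) -> list[EventMention]:
    """Both extraction steps plus polarity and negation for one sentence."""
    simple = extract_simple_events(sentence, mentions, grammar, doc_id, sent_index)
    pool = simple + (extra_events or [])
    nested = extract_nested_events(
        sentence, mentions, pool, grammar, doc_id, sent_index
    )
    events = simple + nested
    apply_polarity(events, sentence, polarity_lexicon)
    apply_negation(events, sentence)
    return events


def extract_document(
    document: Document,
    kb: KB,
    grammar: Grammar | None = None,
    resolve_coref: bool = True,
    polarity_lexicon: PolarityLexicon | None = None,
    max_coref_rounds: int = 3,
) -> ExtractionResult:
    grammar = grammar or load_default_grammar()
    result = ExtractionResult(doc_id=document.doc_id)
    per_sent_mentions: dict[int, list[EntityMention]] = {}
    for si, sent in enumerate(document.sentences):
        mentions = match_entities(sent, kb, document.doc_id, si, grammar)
        for m in mentions:
            if not m.generic:
                ground(m, kb)
        attach_states(sent, mentions)
        per_sent_mentions[si] = mentions
        result.mentions.extend(mentions)
        result.events.extend(
            extract_sentence_events(
                sent, mentions, grammar, document.doc_id, si,
                polarity_lexicon=polarity_lexicon,
            )
        )
    if resolve_coref:
        for _ in range(max_coref_rounds):
            new_links, new_events = resolve_and_reextract(
                document, result, per_sent_mentions, kb, grammar, polarity_lexicon
            )
            result.links = new_links
            if not new_events:
                break
            result.events.extend(new_events)
    return result


def resolve_and_reextract(
    document: Document,
    result: ExtractionResult,
    per_sent_mentions: dict[int, list[EntityMention]],
    kb: KB,
    grammar: Grammar,
    polarity_lexicon: PolarityLexicon | None = None,
) -> tuple[list[CorefLink], list[EventMention]]:
    """Resolve anaphors and re-run extraction on affected sentences.

    Returns the full link set plus only the events not previously seen;
    those carry coref provenance.
    """
    anaphors = find_anaphors(document, result.mentions, result.events)
    links = apply_sieves(document, anaphors, result.mentions, result.events)
    known = {ev.key() for ev in result.events}
    new_events: list[EventMention] = []
    by_sentence: dict[int, list[CorefLink]] = {}
    for link in links:
        by_sentence.setdefault(link.anaphor.sent_index, []).append(link)
    for si, sent_links in sorted(by_sentence.items()):
        sent = document.sentences[si]
        mentions = list(per_sent_mentions.get(si, []))
        extra_events: list[EventMention] = []
        for link in sent_links:
            am = alias_mention(link, document.doc_id)
            if am is not None:
                mentions.append(am)
            ae = alias_event(link)
            if ae is not None:
                extra_events.append(ae)
        events = extract_sentence_events(
            sent, mentions, grammar, document.doc_id, si,
            extra_events=extra_events, polarity_lexicon=polarity_lexicon,
        )
        for ev in events:
            if ev.key() in known:
                continue
            known.add(ev.key())
            ev.coref = True
            new_events.append(ev)
    return links, new_events
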