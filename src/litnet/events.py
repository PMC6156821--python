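"""Two-step bottom-up event extraction.

Step one finds simple events (the nine covalent additions, their
removal mirrors, binding, hydrolysis, translocation) directly on entity
mentions; any cause bound by a simple-event rule is held aside.  Step
two wraps held causes into positive regulations and matches explicit
control triggers over events (regulations) or entities (activations).
Coordination is expanded to the full conjunct cross-product before
events are built, and negation cues governing a trigger set the negated
flag with parity semantics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from litnet.entities import EntityMention
from litnet.grammar.engine import (
    EVENT_CATEGORIES,
    Grammar,
    PatternMatch,
)
from litnet.preprocess import Sentence

log = logging.getLogger(__name__)

SIMPLE_CATEGORIES = ("simple_event", "binding", "hydrolysis", "translocation")
NESTED_CATEGORIES = (
    "positive_regulation_activation",
    "negative_regulation_activation",
)

REGULATION_LABELS = {
    +1: "positive_regulation",
    -1: "negative_regulation",
}
ACTIVATION_LABELS = {
    +1: "positive_activation",
    -1: "negative_activation",
}

#: negation cue forms (configurable at call sites)
NEGATION_CUES = frozenset(
    {"not", "no", "never", "n't", "without", "cannot", "unable", "fail",
     "fails", "failed", "failing", "lack", "lacks", "lacked"}
)


@dataclass
class EventMention:
    doc_id: str
    sent_index: int
    label: str
    trigger: tuple[int, int]  # token span
    trigger_text: str
    arguments: dict[str, list] = field(default_factory=dict)  # role -> mentions/events
    sign: int = +1
    negated: bool = False
    rule: str = ""
    coref: bool = False
    #: causes captured by a simple-event rule, held for step two
    held_causes: list[EntityMention] = field(default_factory=list)
    #: cause-promoted regulations reuse the inner event's trigger span;
    #: they have no surface trigger of their own and must not be bound
    #: as arguments by token position
    synthetic_trigger: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.trigger

    def is_nested(self) -> bool:
        return self.label in (
            "positive_regulation",
            "negative_regulation",
            "positive_activation",
            "negative_activation",
        )

    def key(self) -> tuple:
        args = []
        for role in sorted(self.arguments):
            for a in self.arguments[role]:
                if isinstance(a, EntityMention):
                    args.append((role, "m", a.sent_index, a.span))
                else:
                    args.append((role, "e", a.key()))
        return (self.label, self.sent_index, self.trigger, tuple(args), self.negated)

    def participants(self) -> list:
        return [a for vals in self.arguments.values() for a in vals]


# ---------------------------------------------------------------------
# coordination expansion
# ---------------------------------------------------------------------


def _conj_set(sentence: Sentence, tok: int) -> list[int]:
    """Token plus everything reachable over conj edges (either way)."""
    out = {tok}
    frontier = [tok]
    while frontier:
        cur = frontier.pop()
        for d, lbl in sentence.children(cur):
            if lbl == "conj" and d not in out:
                out.add(d)
                frontier.append(d)
        head = sentence.head_of(cur)
        if head and head[1] == "conj" and head[0] >= 0 and head[0] not in out:
            out.add(head[0])
            frontier.append(head[0])
    return sorted(out)


def expand_coordinations(
    match: PatternMatch,
    sentence: Sentence,
    mentions: Sequence[EntityMention],
    trigger_labels: dict[str, set[str]] | None = None,
    grammar: Grammar | None = None,
) -> list[PatternMatch]:
    """Expand a match over conj-linked triggers and arguments.

    Returns the full cross-product of trigger x argument conjunct sets.
    A conj-linked trigger re-resolves its event label through the
    lexicons (``degrade and ubiquitinate`` yields hydrolysis *and*
    ubiquitination); conj triggers belonging to no lexicon are skipped.
    """
    if not sentence.deps:
        return [match]
    if trigger_labels is None:
        trigger_labels = _trigger_label_index(sentence, grammar) if grammar else {}

    trig_tok = match.trigger[0]
    trig_options: list[tuple[tuple[int, int], str]] = []
    for cand in _conj_set(sentence, trig_tok):
        if cand == trig_tok:
            trig_options.append((match.trigger, match.event_label))
            continue
        labels = trigger_labels.get(_tok_key(sentence, cand), set())
        if match.event_label in labels:
            trig_options.append(((cand, cand + 1), match.event_label))
        else:
            # label swap within the same structural family
            family = _label_family(match.event_label)
            for lbl in sorted(labels):
                if _label_family(lbl) == family:
                    trig_options.append(((cand, cand + 1), lbl))
                    break

    role_options: dict[str, list[tuple[str, object]]] = {}
    for role, (kind, obj) in match.bindings.items():
        opts = [(kind, obj)]
        if kind == "mention":
            for cand in _conj_set(sentence, obj.end - 1):
                m = _mention_covering(mentions, cand)
                if m is not None and m.span != obj.span:
                    opts.append(("mention", m))
        role_options[role] = opts

    out = []
    for (tspan, tlabel), combo in itertools.product(
        trig_options,
        itertools.product(*role_options.values()) if role_options else [()],
    ):
        bindings = dict(zip(role_options.keys(), combo))
        spans = [
            o.span if k == "mention" else getattr(o, "trigger", None)
            for k, o in bindings.values()
        ]
        if len(spans) != len(set(map(repr, spans))):
            continue
        out.append(
            PatternMatch(
                rule=match.rule,
                category=match.category,
                event_label=tlabel,
                sign=match.sign,
                sent_index=match.sent_index,
                trigger=tspan,
                bindings=bindings,
                variation=match.variation,
            )
        )
    seen: set = set()
    uniq = []
    for m in out:
        k = m.binding_key()
        if k not in seen:
            seen.add(k)
            uniq.append(m)
    return uniq


def _tok_key(sentence: Sentence, tok: int) -> tuple[str, str, str]:
    t = sentence.tokens[tok]
    return (t.text.lower(), t.lemma.lower(), t.pos)


def _label_family(label: str) -> str:
    if label in ("positive_regulation", "negative_regulation"):
        return "regulation"
    return "simple"


def _trigger_label_index(
    sentence: Sentence, grammar: Grammar
) -> dict[tuple[str, str, str], set[str]]:
    idx: dict[tuple[str, str, str], set[str]] = {}
    for tok in sentence.tokens:
        key = (tok.text.lower(), tok.lemma.lower(), tok.pos)
        for label, lex in grammar.lexicons.items():
            if label in grammar.aux_lexicons:
                continue
            if lex.matches(tok.text, tok.lemma, tok.pos):
                idx.setdefault(key, set()).add(label)
    return idx


def _mention_covering(mentions: Sequence[EntityMention], tok: int):
    for m in mentions:
        if m.start <= tok < m.end and not m.generic:
            return m
    return None


# ---------------------------------------------------------------------
# binding binarization
# ---------------------------------------------------------------------


def binarize_binding(
    participants: Sequence[EntityMention],
    mode: str = "chain",
) -> list[tuple[EntityMention, EntityMention]]:
    """Decompose an n-ary complex-assembly participant list into pairs.

    ``chain`` (default) links consecutive participants in text order
    (n-1 events); ``all_pairs`` emits every unordered pair.  A single
    participant yields nothing (logged).
    """
    uniq: list[EntityMention] = []
    seen: set = set()
    for p in sorted(participants, key=lambda m: m.start):
        if p.span not in seen:
            seen.add(p.span)
            uniq.append(p)
    if len(uniq) < 2:
        log.warning("binding with %d participant(s) skipped", len(uniq))
        return []
    if mode == "all_pairs":
        return list(itertools.combinations(uniq, 2))
    if mode != "chain":
        raise ValueError(f"unknown binarization mode {mode!r}")
    return list(zip(uniq, uniq[1:]))


# ---------------------------------------------------------------------
# step one: simple events
# ---------------------------------------------------------------------


def _match_to_simple_event(
    match: PatternMatch, sentence: Sentence, doc_id: str
) -> EventMention | None:
    args: dict[str, list] = {}
    held: list[EntityMention] = []
    for role, (kind, obj) in match.bindings.items():
        if kind != "mention":
            continue
        if role == "cause":
            held.append(obj)
        elif role in ("theme1", "theme2"):
            args.setdefault("theme", []).append(obj)
        else:
            args.setdefault(role, []).append(obj)
    if "theme" not in args:
        return None
    if match.category == "binding":
        themes = sorted(args["theme"], key=lambda m: m.start)
        if len({m.span for m in themes}) != 2:
            return None
        args["theme"] = themes
    i, j = match.trigger
    return EventMention(
        doc_id=doc_id,
        sent_index=match.sent_index,
        label=match.event_label,
        trigger=match.trigger,
        trigger_text=sentence.span_text(i, j),
        arguments=args,
        sign=+1,
        rule=match.rule,
        held_causes=held,
    )


def extract_simple_events(
    sentence: Sentence,
    mentions: Sequence[EntityMention],
    grammar: Grammar,
    doc_id: str = "doc",
    sent_index: int = 0,
) -> list[EventMention]:
    """Step one: events operating directly on entities."""
    matches = grammar.match_sentence(
        sentence, mentions, events=(), categories=SIMPLE_CATEGORIES,
        sent_index=sent_index,
    )
    trigger_labels = _trigger_label_index(sentence, grammar)
    expanded: list[PatternMatch] = []
    for m in matches:
        expanded.extend(
            expand_coordinations(m, sentence, mentions, trigger_labels)
        )
    events = []
    for m in expanded:
        ev = _match_to_simple_event(m, sentence, doc_id)
        if ev is not None:
            events.append(ev)
    return _subsume(events)


def _subsume(events: list[EventMention]) -> list[EventMention]:
    """Drop duplicates and events strictly subsumed by a richer sibling.

    Two events with the same label, trigger and theme set collapse onto
    the one carrying the superset of arguments (e.g. the variant that
    also bound a site).
    """
    def core(ev: EventMention) -> tuple:
        themes = tuple(sorted(a.span for a in ev.arguments.get("theme", [])))
        return (ev.label, ev.sent_index, ev.trigger, themes)

    def richness(ev: EventMention) -> tuple:
        return (sum(len(v) for v in ev.arguments.values()), len(ev.held_causes))

    best: dict[tuple, EventMention] = {}
    for ev in events:
        k = core(ev)
        cur = best.get(k)
        if cur is None:
            best[k] = ev
        else:
            if richness(ev) > richness(cur):
                ev.held_causes = list({id(c): c for c in cur.held_causes + ev.held_causes}.values())
                best[k] = ev
            else:
                merged = {id(c): c for c in cur.held_causes + ev.held_causes}
                cur.held_causes = list(merged.values())
    # exact-duplicate collapse across differing triggers is intentional:
    # distinct triggers stay distinct events
    out = []
    seen: set = set()
    for ev in best.values():
        if ev.key() not in seen:
            seen.add(ev.key())
            out.append(ev)
    return out


# ---------------------------------------------------------------------
# step two: nested events
# ---------------------------------------------------------------------


def _nested_label(sign: int, controlled) -> str:
    if isinstance(controlled, EventMention):
        return REGULATION_LABELS[sign]
    return ACTIVATION_LABELS[sign]


def extract_nested_events(
    sentence: Sentence,
    mentions: Sequence[EntityMention],
    simple_events: Sequence[EventMention],
    grammar: Grammar,
    doc_id: str = "doc",
    sent_index: int = 0,
    max_depth: int = 3,
) -> list[EventMention]:
    """Step two: regulations and activations over step-one output.

    Control verbs whose controlled argument resolves to an event become
    regulations; those resolving to an entity become activations.  Held
    causes from step one are promoted to positive regulations.  Chains
    (regulation of a regulation) are found by iterating to a fixpoint.
    """
    nested: list[EventMention] = []
    seen: set = set()

    def dedupe_key(label, controller, controlled) -> tuple:
        ck = controller.span if isinstance(controller, EntityMention) else controller.key()
        dk = controlled.span if isinstance(controlled, EntityMention) else controlled.key()
        return (label, sent_index, repr(ck), repr(dk))

    # cause promotion
    for ev in simple_events:
        for cause in ev.held_causes:
            label = REGULATION_LABELS[+1]
            k = dedupe_key(label, cause, ev)
            if k in seen:
                continue
            seen.add(k)
            nested.append(
                EventMention(
                    doc_id=doc_id,
                    sent_index=sent_index,
                    label=label,
                    trigger=ev.trigger,
                    trigger_text=ev.trigger_text,
                    arguments={"controller": [cause], "controlled": [ev]},
                    sign=+1,
                    rule=f"{ev.rule}+cause-promotion",
                    synthetic_trigger=True,
                )
            )

    trigger_labels = _trigger_label_index(sentence, grammar)
    for _ in range(max_depth):
        pool = list(simple_events) + nested
        matches = grammar.match_sentence(
            sentence, mentions, events=pool, categories=NESTED_CATEGORIES,
            sent_index=sent_index,
        )
        expanded: list[PatternMatch] = []
        for m in matches:
            expanded.extend(
                expand_coordinations(m, sentence, mentions, trigger_labels)
            )
        added = False
        for m in expanded:
            ctrl = m.bindings.get("controller")
            ctld = m.bindings.get("controlled")
            if not ctrl or not ctld:
                continue
            controller = ctrl[1]
            controlled = ctld[1]
            if isinstance(controlled, EventMention) and _contains(controlled, controller):
                continue  # acyclicity guard
            label = _nested_label(m.sign, controlled)
            k = dedupe_key(label, controller, controlled)
            if k in seen:
                continue
            seen.add(k)
            added = True
            i, j = m.trigger
            nested.append(
                EventMention(
                    doc_id=doc_id,
                    sent_index=sent_index,
                    label=label,
                    trigger=m.trigger,
                    trigger_text=sentence.span_text(i, j),
                    arguments={"controller": [controller], "controlled": [controlled]},
                    sign=m.sign,
                    rule=m.rule,
                )
            )
        if not added:
            break
    return nested


def _contains(event: EventMention, other) -> bool:
    if event is other:
        return True
    for arg in event.participants():
        if isinstance(arg, EventMention) and _contains(arg, other):
            return True
    return False


# ---------------------------------------------------------------------
# negation
# ---------------------------------------------------------------------


def detect_negation(
    event: EventMention,
    sentence: Sentence,
    cues: frozenset[str] = NEGATION_CUES,
) -> bool:
    """True when an odd number of negation cues governs the trigger.

    The governing context is the trigger plus ancestors reached through
    clause-internal labels (xcomp/aux/cop); cue ancestors themselves
    ("fails to ...") and cue dependents ("did not ...") both count, and
    double negation cancels by parity.
    """
    if not sentence.deps:
        return event.negated
    chain = [event.trigger[0]]
    cur = event.trigger[0]
    while True:
        head = sentence.head_of(cur)
        if head is None or head[0] < 0 or head[1] not in ("xcomp", "aux", "auxpass", "cop"):
            break
        cur = head[0]
        chain.append(cur)
    count = 0
    for node in chain[1:]:
        t = sentence.tokens[node]
        if t.text.lower() in cues or t.lemma.lower() in cues:
            count += 1
    for node in chain:
        for d, lbl in sentence.children(node):
            if lbl in ("neg", "advmod", "det", "case", "mark"):
                t = sentence.tokens[d]
                if t.text.lower() in cues or t.lemma.lower() in cues:
                    count += 1
    return count % 2 == 1


def apply_negation(events: Iterable[EventMention], sentence: Sentence) -> None:
    for ev in events:
        ev.negated = detect_negation(ev, sentence)
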