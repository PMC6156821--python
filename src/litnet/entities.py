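"""Entity recognition, grounding and state attachment.

The recognizer is a hybrid of dictionary matching against knowledge-base
(KB) TSV files and token-pattern rules from the shipped grammar (sites
such as ``Ser37``, cellular components).  A pluggable statistical tagger
contract exists for completeness; on overlap the rule-based output wins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, TextIO

from litnet.preprocess import Sentence

ENTITY_TYPES = (
    "gene_or_gene_product",
    "family",
    "simple_chemical",
    "site",
    "cellular_component",
)

#: the nine covalent-modification reaction types
PTM_SUBTYPES = (
    "phosphorylation",
    "ubiquitination",
    "hydroxylation",
    "sumoylation",
    "glycosylation",
    "acetylation",
    "farnesylation",
    "ribosylation",
    "methylation",
)

#: KB priority used to order groundings (configurable per-call)
DEFAULT_KB_PRIORITY = ("uniprot", "interpro", "chebi", "hmdb", "uaz")

MUTANT_VARIANT_RE = re.compile(r"^[A-Z]\d+[A-Z]$")

_PTM_PREFIXES = {
    "phospho": "phosphorylation",
    "ubiquitinated": "ubiquitination",
    "ubiquityl": "ubiquitination",
    "acetyl": "acetylation",
    "methyl": "methylation",
    "sumo": "sumoylation",
    "glycosyl": "glycosylation",
    "hydroxyl": "hydroxylation",
    "farnesyl": "farnesylation",
    "ribosyl": "ribosylation",
}
_PTM_PARTICIPLES = {
    "phosphorylated": "phosphorylation",
    "ubiquitinated": "ubiquitination",
    "hydroxylated": "hydroxylation",
    "sumoylated": "sumoylation",
    "glycosylated": "glycosylation",
    "acetylated": "acetylation",
    "farnesylated": "farnesylation",
    "ribosylated": "ribosylation",
    "methylated": "methylation",
}


class KBLoadError(ValueError):
    pass


@dataclass(frozen=True)
class KBEntry:
    namespace: str
    identifier: str
    canonical: str
    synonyms: tuple[str, ...]
    entity_type: str

    def names(self) -> tuple[str, ...]:
        return (self.canonical, *self.synonyms)


@dataclass(frozen=True)
class Modification:
    kind: str  # "PTM" | "Mutant" | "WildType"
    subtype: str | None = None  # PTM reaction type
    variant: str | None = None  # e.g. "K134A"
    site: str | None = None
    evidence: tuple[int, int] | None = None  # token span

    def __post_init__(self) -> None:
        if self.kind == "PTM" and self.subtype not in PTM_SUBTYPES:
            raise ValueError(f"unknown PTM subtype {self.subtype!r}")


@dataclass
class EntityMention:
    doc_id: str
    sent_index: int
    start: int  # token index, half-open
    end: int
    text: str
    entity_type: str
    groundings: list[tuple[str, str]] = field(default_factory=list)
    modifications: list[Modification] = field(default_factory=list)
    #: generic NPs ("this protein") are coref anaphor candidates and are
    #: never bound as event arguments until resolved
    generic: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def grounding_id(self) -> str | None:
        if not self.groundings:
            return None
        ns, ident = self.groundings[0]
        return f"{ns}:{ident}"

    def key(self) -> tuple:
        return (self.doc_id, self.sent_index, self.start, self.end, self.entity_type)


class KB:
    """Index over KB entries supporting exact and case-insensitive lookup."""

    def __init__(self) -> None:
        self.entries: list[KBEntry] = []
        self._exact: dict[str, list[KBEntry]] = {}
        self._folded: dict[str, list[KBEntry]] = {}
        self.max_name_tokens = 1

    def add(self, entry: KBEntry) -> None:
        for existing in self.entries:
            if (
                existing.namespace == entry.namespace
                and existing.identifier == entry.identifier
                and existing.entity_type != entry.entity_type
            ):
                raise KBLoadError(
                    f"conflicting entity_type for {entry.namespace}:{entry.identifier}"
                )
        self.entries.append(entry)
        for name in entry.names():
            self._exact.setdefault(name, []).append(entry)
            self._folded.setdefault(name.casefold(), []).append(entry)
            self.max_name_tokens = max(self.max_name_tokens, _name_token_count(name))

    def lookup(self, name: str) -> list[KBEntry]:
        hits = self._exact.get(name)
        if hits:
            return list(hits)
        return list(self._folded.get(name.casefold(), []))

    def __len__(self) -> int:
        return len(self.entries)


def _name_token_count(name: str) -> int:
    # mirrors the tokenizer: separators become their own tokens
    return len(re.findall(r"\d+(?:[.,]\d+)+|\w+|[^\w\s]", name))


def load_kb(stream: TextIO | Iterable[str]) -> KB:
    """Load a 5-column TSV (namespace, id, canonical, synonyms, type).

    Synonyms are pipe-separated and deduplicated case-insensitively.
    """
    kb = KB()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise KBLoadError(f"line {lineno}: expected 5 columns, got {len(cols)}")
        ns, ident, canonical, syns, etype = cols
        if not ident:
            raise KBLoadError(f"line {lineno}: empty identifier")
        if etype not in ENTITY_TYPES:
            raise KBLoadError(f"line {lineno}: unknown entity type {etype!r}")
        seen: set[str] = {canonical.casefold()}
        synonyms = []
        for s in syns.split("|"):
            s = s.strip()
            if s and s.casefold() not in seen:
                seen.add(s.casefold())
                synonyms.append(s)
        kb.add(KBEntry(ns, ident, canonical, tuple(synonyms), etype))
    return kb


# ---------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------

#: optional statistical tagger contract: sentence -> candidate mentions.
#: Disabled by default; on overlap with rule-based output the rule wins.
StatisticalTagger = Callable[[Sentence], list[EntityMention]]


def dictionary_candidates(
    sentence: Sentence, kb: KB, doc_id: str = "doc", sent_index: int = 0
) -> list[EntityMention]:
    """All KB-name hits over token n-grams (may overlap)."""
    out: list[EntityMention] = []
    n = len(sentence.tokens)
    max_len = min(n, kb.max_name_tokens)
    for i in range(n):
        for j in range(i + 1, min(n, i + max_len) + 1):
            text = sentence.span_text(i, j)
            hits = kb.lookup(text)
            if hits:
                out.append(
                    EntityMention(
                        doc_id=doc_id,
                        sent_index=sent_index,
                        start=i,
                        end=j,
                        text=text,
                        entity_type=hits[0].entity_type,
                    )
                )
    return out


def select_non_overlapping(candidates: list[EntityMention]) -> list[EntityMention]:
    """Longest-match-wins with leftmost-first tie-breaking."""
    ranked = sorted(candidates, key=lambda m: (-(m.end - m.start), m.start))
    taken: list[EntityMention] = []
    for cand in ranked:
        if all(cand.end <= t.start or cand.start >= t.end for t in taken):
            taken.append(cand)
    return sorted(taken, key=lambda m: m.start)


def match_entities(
    sentence: Sentence,
    kb: KB,
    doc_id: str = "doc",
    sent_index: int = 0,
    grammar=None,
    tagger: StatisticalTagger | None = None,
) -> list[EntityMention]:
    """Recognize entity mentions: KB dictionary + grammar pattern rules.

    ``grammar`` defaults to the shipped grammar; pass ``False`` to use
    dictionary matching only.  Output spans never overlap.
    """
    candidates = dictionary_candidates(sentence, kb, doc_id, sent_index)
    if grammar is None:
        from litnet.grammar import load_default_grammar

        grammar = load_default_grammar()
    if grammar:
        candidates.extend(grammar.entity_mentions(sentence, doc_id, sent_index))
    rule_based = select_non_overlapping(candidates)
    if tagger is not None:
        extra = [
            m
            for m in tagger(sentence)
            if all(m.end <= r.start or m.start >= r.end for r in rule_based)
        ]
        rule_based = sorted(rule_based + extra, key=lambda m: m.start)
    return rule_based


# ---------------------------------------------------------------------
# grounding
# ---------------------------------------------------------------------


def _local_id(mention: EntityMention) -> str:
    slug = re.sub(r"[^A-Za-z0-9]+", "-", mention.text).strip("-").upper() or "X"
    return f"UAZ-{mention.entity_type[:4].upper()}-{slug}"


def ground(
    mention: EntityMention,
    kb: KB,
    priority: tuple[str, ...] = DEFAULT_KB_PRIORITY,
) -> EntityMention:
    """Attach KB identifiers ordered by namespace priority.

    Pattern-only mentions receive a deterministic local ``uaz`` id.
    Idempotent: already-grounded mentions are returned unchanged.
    """
    if mention.groundings:
        return mention
    hits = kb.lookup(mention.text)
    hits = [h for h in hits if h.entity_type == mention.entity_type] or hits

    def rank(entry: KBEntry) -> tuple[int, str]:
        try:
            p = priority.index(entry.namespace)
        except ValueError:
            p = len(priority)
        return (p, entry.identifier)

    if hits:
        seen: set[tuple[str, str]] = set()
        for entry in sorted(hits, key=rank):
            g = (entry.namespace, entry.identifier)
            if g not in seen:
                seen.add(g)
                mention.groundings.append(g)
    else:
        mention.groundings.append(("uaz", _local_id(mention)))
    return mention


# ---------------------------------------------------------------------
# states (PTMs, mutants, wild type)
# ---------------------------------------------------------------------


def attach_states(
    sentence: Sentence, mentions: list[EntityMention]
) -> list[EntityMention]:
    """Detect state-change markers adjacent to entity mentions.

    Handles ``wild type X`` / ``X-WT``, ``X-K134A`` / ``K134A mutant of
    X`` / ``X mutant``, and ``phospho-X`` / ``phosphorylated X``.
    Modifications are appended in place and the list is returned.
    """
    toks = sentence.tokens
    for m in mentions:
        i, j = m.start, m.end
        before = [t.text for t in toks[max(0, i - 3) : i]]
        lowered = [b.lower() for b in before]

        # wild type X  |  wild-type X
        if lowered[-2:] == ["wild", "type"] or lowered[-3:] == ["wild", "-", "type"]:
            _add(m, Modification("WildType", evidence=(i - 2, i)))
        # phosphorylated X  (participle)
        elif before and lowered[-1] in _PTM_PARTICIPLES:
            _add(m, Modification("PTM", subtype=_PTM_PARTICIPLES[lowered[-1]], evidence=(i - 1, i)))
        # phospho-X
        elif len(before) >= 2 and before[-1] == "-" and lowered[-2] in _PTM_PREFIXES:
            _add(m, Modification("PTM", subtype=_PTM_PREFIXES[lowered[-2]], evidence=(i - 2, i)))
        # K134A mutant of X
        elif (
            len(before) >= 3
            and MUTANT_VARIANT_RE.match(before[-3])
            and lowered[-2] == "mutant"
            and lowered[-1] == "of"
        ):
            _add(m, Modification("Mutant", variant=before[-3], evidence=(i - 3, i)))

        after = toks[j : j + 2]
        if len(after) == 2 and after[0].text == "-":
            nxt = after[1].text
            if nxt == "WT":
                _add(m, Modification("WildType", evidence=(j, j + 2)))
            elif MUTANT_VARIANT_RE.match(nxt):
                _add(m, Modification("Mutant", variant=nxt, evidence=(j, j + 2)))
        elif len(after) >= 1 and after[0].text.lower() == "mutant":
            # "X mutant" with no explicit variant string
            if not any(mod.kind == "Mutant" for mod in m.modifications):
                _add(m, Modification("Mutant", variant=None, evidence=(j, j + 1)))
    return mentions


def _add(mention: EntityMention, mod: Modification) -> None:
    if mod not in mention.modifications:
        mention.modifications.append(mod)
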