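"""Parameterized rule templates in two dialects and their matchers.

A *template* is a named, categorized pattern.  Syntax-dialect patterns
walk labeled dependency edges from a trigger token; surface-dialect
patterns scan linear token windows.  Templates in event categories are
*instantiated* per event label with that label's trigger lexicon,
yielding executable rules; compilation is total — all errors surface at
load time.

Syntax-path DSL (one step per whitespace-separated item)::

    >label      head -> dependent along an edge labeled ``label``
    <label      dependent -> head (the incoming edge must match)
    >a|b        label disjunction
    >label?     optional hop (both the hop and the skip are explored)
    >label@lex  the token reached must belong to auxiliary lexicon ``lex``

Surface DSL: bracketed token specs, e.g.
``[t=wild] [t=-|–] [re=^type$] [mention as=target]`` — keys ``t``
(lower-cased literal alternation), ``re``/``nre`` (full-match regex and
its negation), ``lex`` (trigger-lexicon member), ``pos`` (POS prefix),
``mention`` (an entity mention starts here; consumes its whole span),
``as`` (capture name), ``opt`` (optional), ``gap=N`` (up to N skipped
tokens before this element).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

from litnet.entities import EntityMention
from litnet.preprocess import Sentence

# ---------------------------------------------------------------------
# fixed vocabularies
# ---------------------------------------------------------------------

CATEGORIES = (
    "entity",
    "generic_entity",
    "modification",
    "mutant",
    "simple_event",
    "binding",
    "hydrolysis",
    "translocation",
    "positive_regulation_activation",
    "negative_regulation_activation",
)

EVENT_CATEGORIES = (
    "simple_event",
    "binding",
    "hydrolysis",
    "translocation",
    "positive_regulation_activation",
    "negative_regulation_activation",
)

#: the ten named syntactic variations the template engine implements
VARIATIONS = (
    "declarative",
    "passive",
    "prepositional_nominalization",
    "object_nominalization",
    "subject_nominalization",
    "subject_relative_clause",
    "object_relative_clause",
    "subject_apposition",
    "object_apposition",
    "paraphrastic_causative",
)

PTM_ADDITIONS = (
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
PTM_REMOVALS = tuple(f"de{label}" for label in PTM_ADDITIONS)

#: labels a ``simple_event`` template instantiates over (the Removal
#: mirrors are included); binding/hydrolysis/translocation have their
#: own categories
SIMPLE_EVENT_LABELS = PTM_ADDITIONS + PTM_REMOVALS

CATEGORY_LABELS: dict[str, tuple[str, ...]] = {
    "simple_event": SIMPLE_EVENT_LABELS,
    "binding": ("binding",),
    "hydrolysis": ("hydrolysis",),
    "translocation": ("translocation",),
    "positive_regulation_activation": ("positive_regulation",),
    "negative_regulation_activation": ("negative_regulation",),
}

CATEGORY_SIGN = {
    "positive_regulation_activation": +1,
    "negative_regulation_activation": -1,
}

KNOWN_DEP_LABELS = frozenset(
    {
        "nsubj", "nsubjpass", "obj", "iobj", "csubj", "obl",
        "nmod_of", "nmod_by", "nmod_with", "nmod_to", "nmod_into",
        "nmod_from", "nmod_in", "nmod_at", "nmod_on", "nmod_between",
        "nmod_via", "nmod_for",
        "acl", "acl:relcl", "appos", "compound", "amod", "advmod",
        "conj", "cc", "det", "neg", "mark", "aux", "auxpass", "case",
        "cop", "xcomp", "ccomp", "punct", "dep", "nummod", "expl",
    }
)


class CompileError(ValueError):
    pass


# ---------------------------------------------------------------------
# lexicons
# ---------------------------------------------------------------------


@dataclass
class TriggerLexicon:
    """Trigger forms (with optional POS prefix constraints) per label."""

    label: str
    forms: dict[str, str] = field(default_factory=dict)  # form -> POS prefix ("" = any)

    def matches(self, text: str, lemma: str, pos: str) -> bool:
        for key in (text.lower(), lemma.lower()):
            if key in self.forms:
                want = self.forms[key]
                if not want or pos.startswith(want):
                    return True
        return False

    def __len__(self) -> int:
        return len(self.forms)


def load_lexicons(stream: Iterable[str]) -> dict[str, TriggerLexicon]:
    """Load a 3-column TSV: label, form, POS prefix (may be empty)."""
    out: dict[str, TriggerLexicon] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) not in (2, 3):
            raise CompileError(f"lexicon line {lineno}: expected 2-3 columns")
        label, form = cols[0], cols[1].lower()
        pos = cols[2] if len(cols) == 3 else ""
        out.setdefault(label, TriggerLexicon(label)).forms[form] = pos
    return out


# ---------------------------------------------------------------------
# pattern ASTs
# ---------------------------------------------------------------------

_STEP_RE = re.compile(r"^([<>])([\w:|]+?)(?:@(\w+))?(\?)?$")


@dataclass(frozen=True)
class PathStep:
    down: bool  # True: head -> dependent
    labels: tuple[str, ...]
    gate: str | None = None  # auxiliary lexicon the reached token must hit
    optional: bool = False


def parse_path(expr: str) -> tuple[PathStep, ...]:
    steps = []
    for raw in expr.split():
        m = _STEP_RE.match(raw)
        if m is None:
            raise CompileError(f"bad path step {raw!r} in {expr!r}")
        direction, labels, gate, opt = m.groups()
        label_set = tuple(labels.split("|"))
        for lbl in label_set:
            if lbl not in KNOWN_DEP_LABELS:
                raise CompileError(f"unknown dependency label {lbl!r} in {expr!r}")
        steps.append(
            PathStep(down=direction == ">", labels=label_set, gate=gate, optional=bool(opt))
        )
    if not steps:
        raise CompileError(f"empty path expression {expr!r}")
    return tuple(steps)


@dataclass(frozen=True)
class ArgSpec:
    role: str
    path: tuple[PathStep, ...]
    arg_type: str  # "entity" | "event" | "either" | "site"
    required: bool


@dataclass(frozen=True)
class SurfaceSpec:
    literals: tuple[str, ...] = ()
    regex: str | None = None
    nregex: str | None = None
    lex: bool = False
    mention: bool = False
    pos: str | None = None
    capture: str | None = None
    optional: bool = False
    gap: int = 0


def parse_surface(expr: str) -> tuple[SurfaceSpec, ...]:
    # items are separated by "] [" so regexes may contain "]" freely
    stripped = expr.strip()
    if not (stripped.startswith("[") and stripped.endswith("]")):
        raise CompileError(f"surface pattern must be bracketed items: {expr!r}")
    items = re.split(r"\]\s+\[", stripped[1:-1])
    if not items or items == [""]:
        raise CompileError(f"empty surface pattern {expr!r}")
    specs = []
    for item in items:
        kw: dict[str, object] = {}
        for part in item.split():
            if part == "opt":
                kw["optional"] = True
            elif part == "lex":
                kw["lex"] = True
            elif part == "mention":
                kw["mention"] = True
            elif "=" in part:
                key, val = part.split("=", 1)
                if key == "t":
                    kw["literals"] = tuple(v.lower() for v in val.split("|"))
                elif key == "re":
                    re.compile(val)
                    kw["regex"] = val
                elif key == "nre":
                    re.compile(val)
                    kw["nregex"] = val
                elif key == "pos":
                    kw["pos"] = val
                elif key == "as":
                    kw["capture"] = val
                elif key == "gap":
                    kw["gap"] = int(val)
                else:
                    raise CompileError(f"unknown surface key {key!r} in {expr!r}")
            else:
                raise CompileError(f"bad surface item part {part!r} in {expr!r}")
        specs.append(SurfaceSpec(**kw))  # type: ignore[arg-type]
    return tuple(specs)


# ---------------------------------------------------------------------
# templates and compiled rules
# ---------------------------------------------------------------------


@dataclass
class RuleTemplate:
    name: str
    category: str
    dialect: str  # "syntax" | "surface"
    variation: str | None = None
    trigger_pos: str | None = None
    args: dict[str, dict] = field(default_factory=dict)  # syntax dialect
    forbid: tuple[str, ...] = ()
    pattern: str | None = None  # surface dialect
    entity_type: str | None = None  # entity-category output type
    produces: str | None = None  # modification/mutant semantic tag

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CompileError(f"{self.name}: unknown category {self.category!r}")
        if self.dialect not in ("syntax", "surface"):
            raise CompileError(f"{self.name}: unknown dialect {self.dialect!r}")


@dataclass
class CompiledRule:
    name: str
    template: RuleTemplate
    event_label: str | None
    sign: int
    lexicon: TriggerLexicon | None
    arg_specs: tuple[ArgSpec, ...] = ()
    forbid: tuple[tuple[PathStep, ...], ...] = ()
    surface: tuple[SurfaceSpec, ...] = ()

    @property
    def category(self) -> str:
        return self.template.category

    @property
    def dialect(self) -> str:
        return self.template.dialect

    @property
    def variation(self) -> str | None:
        return self.template.variation


def compile_template(
    template: RuleTemplate,
    lexicon: TriggerLexicon | None,
    event_label: str | None = None,
) -> CompiledRule:
    """Instantiate a template with a trigger lexicon into an executable rule.

    Pattern syntax, dependency labels and lexicon non-emptiness are all
    checked here, so matching never raises.
    """
    is_event = template.category in EVENT_CATEGORIES
    if is_event:
        if lexicon is None or len(lexicon) == 0:
            raise CompileError(
                f"{template.name}: empty trigger lexicon for {event_label!r}"
            )
    if template.dialect == "syntax":
        arg_specs = tuple(
            ArgSpec(
                role=role,
                path=parse_path(spec["path"]),
                arg_type=spec.get("type", "entity"),
                required=bool(spec.get("required", False)),
            )
            for role, spec in template.args.items()
        )
        if is_event and not any(a.required for a in arg_specs):
            raise CompileError(f"{template.name}: no required argument role")
        forbid = tuple(parse_path(f) for f in template.forbid)
        return CompiledRule(
            name=f"{template.name}@{event_label}" if event_label else template.name,
            template=template,
            event_label=event_label,
            sign=CATEGORY_SIGN.get(template.category, +1),
            lexicon=lexicon,
            arg_specs=arg_specs,
            forbid=forbid,
        )
    if not template.pattern:
        raise CompileError(f"{template.name}: surface template without pattern")
    surface = parse_surface(template.pattern)
    if any(s.lex for s in surface) and (lexicon is None or len(lexicon) == 0):
        raise CompileError(f"{template.name}: surface lex item but empty lexicon")
    return CompiledRule(
        name=f"{template.name}@{event_label}" if event_label else template.name,
        template=template,
        event_label=event_label,
        sign=CATEGORY_SIGN.get(template.category, +1),
        lexicon=lexicon,
        surface=surface,
    )


# ---------------------------------------------------------------------
# matches
# ---------------------------------------------------------------------


@dataclass
class PatternMatch:
    rule: str
    category: str
    event_label: str | None
    sign: int
    sent_index: int
    trigger: tuple[int, int]  # token span
    bindings: dict[str, tuple[str, object]] = field(default_factory=dict)
    variation: str | None = None

    def binding_key(self) -> tuple:
        items = []
        for role in sorted(self.bindings):
            kind, obj = self.bindings[role]
            if kind == "mention":
                items.append((role, kind, obj.span))
            elif kind == "event":
                items.append((role, kind, obj.key()))
            else:
                items.append((role, kind, obj))
        return (self.event_label, self.trigger, tuple(items))


# ---------------------------------------------------------------------
# dependency matcher
# ---------------------------------------------------------------------


def _walk_path(
    sentence: Sentence,
    start: int,
    steps: Sequence[PathStep],
    aux_lexicons: dict[str, TriggerLexicon],
) -> set[int]:
    """All tokens reachable from ``start`` by consuming ``steps``."""
    frontier = {start}
    for step in steps:
        nxt: set[int] = set(frontier) if step.optional else set()
        for tok in frontier:
            if step.down:
                hops = [d for d, lbl in sentence.children(tok) if lbl in step.labels]
            else:
                head = sentence.head_of(tok)
                hops = [head[0]] if head and head[1] in step.labels and head[0] >= 0 else []
            for h in hops:
                if step.gate is not None:
                    lex = aux_lexicons.get(step.gate)
                    t = sentence.tokens[h]
                    if lex is None or not lex.matches(t.text, t.lemma, t.pos):
                        continue
                nxt.add(h)
        frontier = nxt
        if not frontier:
            break
    return frontier


def _mention_at(mentions: Sequence[EntityMention], tok: int) -> EntityMention | None:
    for m in mentions:
        if m.start <= tok < m.end and not getattr(m, "generic", False):
            return m
    return None


def _events_at(events: Sequence, tok: int) -> list:
    return [
        e
        for e in events
        if e.trigger[0] <= tok < e.trigger[1]
        and not getattr(e, "synthetic_trigger", False)
    ]


def match_dependency_pattern(
    rule: CompiledRule,
    sentence: Sentence,
    mentions: Sequence[EntityMention],
    events: Sequence = (),
    sent_index: int = 0,
    aux_lexicons: dict[str, TriggerLexicon] | None = None,
) -> list[PatternMatch]:
    """Run one syntax-dialect rule over a dependency-annotated sentence."""
    aux_lexicons = aux_lexicons or {}
    out: list[PatternMatch] = []
    if not sentence.deps:
        return out
    tpos = rule.template.trigger_pos
    for tok in sentence.tokens:
        if rule.lexicon is not None and not rule.lexicon.matches(tok.text, tok.lemma, tok.pos):
            continue
        if tpos and not tok.pos.startswith(tpos):
            continue
        if any(
            _walk_path(sentence, tok.index, f, aux_lexicons) for f in rule.forbid
        ):
            continue
        role_options: dict[str, list[tuple[str, object]]] = {}
        dead = False
        for spec in rule.arg_specs:
            landed = _walk_path(sentence, tok.index, spec.path, aux_lexicons)
            opts: list[tuple[str, object]] = []
            for cand in sorted(landed):
                if cand == tok.index:
                    continue
                if spec.arg_type in ("event", "either"):
                    for ev in _events_at(events, cand):
                        opts.append(("event", ev))
                if spec.arg_type in ("entity", "either", "site") and not any(
                    k == "event" and o.trigger[0] <= cand < o.trigger[1]
                    for k, o in opts
                ):
                    m = _mention_at(mentions, cand)
                    if m is not None:
                        if spec.arg_type == "site" and m.entity_type != "site":
                            continue
                        opts.append(("mention", m))
            # dedupe preserving order
            seen: set = set()
            uniq = []
            for kind, obj in opts:
                key = (kind, obj.span if kind == "mention" else obj.key())
                if key not in seen:
                    seen.add(key)
                    uniq.append((kind, obj))
            if spec.required and not uniq:
                dead = True
                break
            role_options[spec.role] = uniq
        if dead:
            continue
        out.extend(
            _cross_product(rule, sent_index, (tok.index, tok.index + 1), role_options)
        )
    return _dedupe(out)


def _cross_product(
    rule: CompiledRule,
    sent_index: int,
    trigger: tuple[int, int],
    role_options: dict[str, list[tuple[str, object]]],
) -> list[PatternMatch]:
    roles = [r for r in role_options]
    combos: list[dict[str, tuple[str, object]]] = [{}]
    for role in roles:
        opts = role_options[role]
        if not opts:
            continue
        combos = [dict(c, **{role: o}) for c in combos for o in opts]
    out = []
    for bindings in combos:
        if not _distinct_participants(bindings):
            continue
        out.append(
            PatternMatch(
                rule=rule.name,
                category=rule.category,
                event_label=rule.event_label,
                sign=rule.sign,
                sent_index=sent_index,
                trigger=trigger,
                bindings=bindings,
                variation=rule.variation,
            )
        )
    return out


def _distinct_participants(bindings: dict[str, tuple[str, object]]) -> bool:
    spans = []
    for kind, obj in bindings.values():
        spans.append(obj.span if kind == "mention" else obj.key())
    return len(spans) == len(set(map(repr, spans)))


def _dedupe(matches: list[PatternMatch]) -> list[PatternMatch]:
    seen: set = set()
    out = []
    for m in matches:
        k = (m.rule, m.binding_key())
        if k not in seen:
            seen.add(k)
            out.append(m)
    return out


# ---------------------------------------------------------------------
# surface matcher
# ---------------------------------------------------------------------


def match_surface_pattern(
    rule: CompiledRule,
    sentence: Sentence,
    mentions: Sequence[EntityMention] = (),
    sent_index: int = 0,
) -> list[PatternMatch]:
    """Run one surface-dialect rule left-to-right over the token sequence."""
    out: list[PatternMatch] = []
    n = len(sentence.tokens)
    mention_by_start: dict[int, EntityMention] = {}
    for m in mentions:
        cur = mention_by_start.get(m.start)
        if cur is None or m.end > cur.end:
            mention_by_start[m.start] = m
    claimed: set[int] = set()
    for start in range(n):
        res = _surf_match_here(rule, sentence, mention_by_start, start, 0, {})
        if res is None:
            continue
        end, captures = res
        span = set(range(start, end))
        if span & claimed:
            continue  # no overlap within one rule, left-to-right
        claimed |= span
        trig = captures.get("trigger", (start, end))
        bindings = {
            name: val for name, val in captures.items() if name != "trigger"
        }
        out.append(
            PatternMatch(
                rule=rule.name,
                category=rule.category,
                event_label=rule.event_label,
                sign=rule.sign,
                sent_index=sent_index,
                trigger=trig if isinstance(trig, tuple) else trig.span,
                bindings=bindings,
                variation=rule.variation,
            )
        )
    return out


def _surf_match_here(
    rule: CompiledRule,
    sentence: Sentence,
    mention_by_start: dict[int, EntityMention],
    pos: int,
    spec_i: int,
    captures: dict,
):
    if spec_i == len(rule.surface):
        return pos, captures
    spec = rule.surface[spec_i]
    n = len(sentence.tokens)
    # try skipping an optional element first? No: prefer consuming.
    for gap in range(0, spec.gap + 1):
        at = pos + gap
        if at >= n:
            break
        got = _surf_item_at(rule, spec, sentence, mention_by_start, at)
        if got is None:
            continue
        consumed, value = got
        new_caps = captures
        if spec.capture:
            new_caps = dict(captures)
            new_caps[spec.capture] = value
        res = _surf_match_here(
            rule, sentence, mention_by_start, at + consumed, spec_i + 1, new_caps
        )
        if res is not None:
            return res
    if spec.optional:
        return _surf_match_here(
            rule, sentence, mention_by_start, pos, spec_i + 1, captures
        )
    return None


def _surf_item_at(
    rule: CompiledRule,
    spec: SurfaceSpec,
    sentence: Sentence,
    mention_by_start: dict[int, EntityMention],
    at: int,
):
    tok = sentence.tokens[at]
    # unannotated tokens (POS "_") pass POS constraints: surface event
    # rules are the fallback for text that never saw a parser
    pos_ok = (
        not spec.pos or tok.pos in ("_", "") or tok.pos.startswith(spec.pos)
    )
    if spec.mention:
        m = mention_by_start.get(at)
        if m is None or not pos_ok:
            return None
        return m.end - m.start, ("mention", m)
    if not pos_ok:
        return None
    if spec.literals and tok.text.lower() not in spec.literals:
        return None
    if spec.regex and not re.fullmatch(spec.regex, tok.text):
        return None
    if spec.nregex and re.fullmatch(spec.nregex, tok.text):
        return None
    if spec.lex:
        if rule.lexicon is None or not rule.lexicon.matches(tok.text, tok.lemma, tok.pos):
            return None
    return 1, (at, at + 1)


# ---------------------------------------------------------------------
# grammar container
# ---------------------------------------------------------------------


class Grammar:
    """A loaded template inventory plus lexicons, compiled and runnable."""

    def __init__(
        self,
        templates: list[RuleTemplate],
        lexicons: dict[str, TriggerLexicon],
    ) -> None:
        names = [t.name for t in templates]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CompileError(f"duplicate template names: {dupes}")
        self.templates = templates
        self.lexicons = lexicons
        self.aux_lexicons = {
            k: v for k, v in lexicons.items() if k not in self._event_labels()
        }
        self.rules: list[CompiledRule] = []
        for t in templates:
            if t.category in EVENT_CATEGORIES:
                for label in CATEGORY_LABELS[t.category]:
                    lex = lexicons.get(label)
                    if lex is None or len(lex) == 0:
                        raise CompileError(f"no trigger lexicon for label {label!r}")
                    self.rules.append(compile_template(t, lex, label))
            else:
                self.rules.append(compile_template(t, None))

    @staticmethod
    def _event_labels() -> set[str]:
        out: set[str] = set()
        for labels in CATEGORY_LABELS.values():
            out.update(labels)
        return out

    # -- inventory -----------------------------------------------------
    def inventory(self) -> dict[str, tuple[int, int]]:
        counts: dict[str, list[int]] = {c: [0, 0] for c in CATEGORIES}
        for t in self.templates:
            counts[t.category][0 if t.dialect == "syntax" else 1] += 1
        return {c: (s, f) for c, (s, f) in counts.items()}

    def total_templates(self) -> int:
        return len(self.templates)

    def variations(self) -> tuple[str, ...]:
        """The registered base syntactic variations (combo tags split)."""
        seen: set[str] = set()
        for t in self.templates:
            if t.variation:
                for v in t.variation.split("+"):
                    seen.add(v)
        return tuple(v for v in VARIATIONS if v in seen)

    # -- execution -----------------------------------------------------
    def rules_for(self, categories: Iterable[str]) -> list[CompiledRule]:
        cats = set(categories)
        return [r for r in self.rules if r.category in cats]

    def entity_mentions(
        self, sentence: Sentence, doc_id: str = "doc", sent_index: int = 0
    ) -> list[EntityMention]:
        """Run entity/generic-entity surface rules -> pattern mentions."""
        out: list[EntityMention] = []
        for rule in self.rules_for(("entity", "generic_entity")):
            for m in match_surface_pattern(rule, sentence, (), sent_index):
                i, j = m.trigger
                # the whole matched window is the mention span
                spans = [m.trigger] + [
                    v.span if k == "mention" else v for k, v in m.bindings.values()
                ]
                i = min(s[0] for s in spans)
                j = max(s[1] for s in spans)
                out.append(
                    EntityMention(
                        doc_id=doc_id,
                        sent_index=sent_index,
                        start=i,
                        end=j,
                        text=sentence.span_text(i, j),
                        entity_type=rule.template.entity_type or "gene_or_gene_product",
                        generic=rule.category == "generic_entity",
                    )
                )
        return out

    def match_sentence(
        self,
        sentence: Sentence,
        mentions: Sequence[EntityMention],
        events: Sequence = (),
        categories: Iterable[str] = EVENT_CATEGORIES,
        sent_index: int = 0,
        surface_fallback_only: bool = True,
    ) -> list[PatternMatch]:
        """Run all rules of ``categories``; order-independent match set.

        Surface event rules act as a fallback for unparsed sentences
        unless ``surface_fallback_only`` is False.
        """
        has_parse = bool(sentence.deps)
        out: list[PatternMatch] = []
        for rule in self.rules_for(categories):
            if rule.dialect == "syntax":
                out.extend(
                    match_dependency_pattern(
                        rule, sentence, mentions, events, sent_index, self.aux_lexicons
                    )
                )
            else:
                if rule.category in EVENT_CATEGORIES and surface_fallback_only and has_parse:
                    continue
                out.extend(match_surface_pattern(rule, sentence, mentions, sent_index))
        return _dedupe(out)


# ---------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------

_default_grammar: Grammar | None = None


def load_grammar(grammar_yaml: str, lexicon_tsv: Iterable[str]) -> Grammar:
    raw = yaml.safe_load(grammar_yaml)
    templates = []
    for entry in raw["templates"]:
        args = entry.get("args", {}) or {}
        templates.append(
            RuleTemplate(
                name=entry["name"],
                category=entry["category"],
                dialect=entry["dialect"],
                variation=entry.get("variation"),
                trigger_pos=entry.get("trigger_pos"),
                args=args,
                forbid=tuple(entry.get("forbid", ()) or ()),
                pattern=entry.get("pattern"),
                entity_type=entry.get("entity_type"),
                produces=entry.get("produces"),
            )
        )
    lexicons = load_lexicons(lexicon_tsv)
    return Grammar(templates, lexicons)


def load_default_grammar() -> Grammar:
    """Load (and cache) the grammar shipped with the package."""
    global _default_grammar
    if _default_grammar is None:
        pkg = resources.files("litnet.grammar") / "data"
        gy = (pkg / "grammar.yaml").read_text()
        lx = (pkg / "lexicons" / "triggers.tsv").read_text().splitlines()
        _default_grammar = load_grammar(gy, lx)
    return _default_grammar


def grammar_inventory(grammar: Grammar | None = None) -> dict[str, tuple[int, int]]:
    """Per-category (syntax, surface) template counts of a grammar."""
    return (grammar or load_default_grammar()).inventory()
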