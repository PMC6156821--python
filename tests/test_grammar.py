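import itertools

import pytest

from litnet.entities import EntityMention
from litnet.grammar.engine import (
    CATEGORY_LABELS,
    EVENT_CATEGORIES,
    VARIATIONS,
    CompileError,
    Grammar,
    RuleTemplate,
    TriggerLexicon,
    compile_template,
    grammar_inventory,
    match_dependency_pattern,
    match_surface_pattern,
    parse_path,
    parse_surface,
)
from tests.conftest import fixture_by_name

TABLE_COUNTS = {
    "entity": (0, 15),
    "generic_entity": (0, 2),
    "modification": (0, 6),
    "mutant": (0, 9),
    "simple_event": (15, 11),
    "binding": (30, 7),
    "hydrolysis": (8, 2),
    "translocation": (12, 0),
    "positive_regulation_activation": (16, 4),
    "negative_regulation_activation": (14, 3),
}


# ---------------------------------------------------------------- inventory


def test_inventory_per_category(grammar):
    assert grammar_inventory(grammar) == TABLE_COUNTS


def test_inventory_grand_total(grammar):
    assert grammar.total_templates() == 154


def test_inventory_event_total(grammar):
    inv = grammar.inventory()
    assert sum(sum(inv[c]) for c in EVENT_CATEGORIES) == 122


def test_variation_registry_complete(grammar):
    assert grammar.variations() == VARIATIONS
    assert len(grammar.variations()) == 10


# ---------------------------------------------------------------- compilation


def _declarative_template():
    return RuleTemplate(
        name="t-decl",
        category="simple_event",
        dialect="syntax",
        variation="declarative",
        trigger_pos="VB",
        args={"theme": {"path": ">obj", "type": "entity", "required": True}},
    )


def test_compile_declarative_with_lexicon():
    lex = TriggerLexicon("phosphorylation", {"phosphorylates": ""})
    rule = compile_template(_declarative_template(), lex, "phosphorylation")
    assert rule.event_label == "phosphorylation"


def test_compile_empty_lexicon_fails():
    with pytest.raises(CompileError):
        compile_template(_declarative_template(), TriggerLexicon("x"), "x")


def test_compile_unknown_label_fails():
    tpl = _declarative_template()
    tpl.args = {"theme": {"path": ">frobnitz", "required": True}}
    with pytest.raises(CompileError, match="frobnitz"):
        compile_template(tpl, TriggerLexicon("x", {"y": ""}), "x")


def test_compile_is_total_for_shipped_grammar(grammar):
    # every template instantiates for every label in its category
    expected = 0
    for t in grammar.templates:
        if t.category in EVENT_CATEGORIES:
            expected += len(CATEGORY_LABELS[t.category])
        else:
            expected += 1
    assert len(grammar.rules) == expected


def test_duplicate_template_names_rejected(grammar):
    with pytest.raises(CompileError, match="duplicate"):
        Grammar(grammar.templates + [grammar.templates[0]], grammar.lexicons)


def test_parse_path_features():
    steps = parse_path(">nmod_to|nmod_with? <acl:relcl >obj@causative")
    assert steps[0].optional and steps[0].labels == ("nmod_to", "nmod_with")
    assert not steps[1].down
    assert steps[2].gate == "causative"


def test_parse_surface_rejects_bad_keys():
    with pytest.raises(CompileError):
        parse_surface("[frob=1]")


# ---------------------------------------------------------------- dependency matching


def _rules_named(grammar, prefix, label):
    return [
        r for r in grammar.rules
        if r.dialect == "syntax" and r.name.startswith(prefix)
        and (label is None or r.event_label == label)
    ]


def test_declarative_match(grammar, corpus, kb):
    from litnet.entities import match_entities

    fx = fixture_by_name(corpus, "vb-paraphrastic")
    sent = fx.document.sentences[0]
    mentions = match_entities(sent, kb, grammar=grammar)
    [rule] = _rules_named(grammar, "se-paraphrastic-causative@", "phosphorylation")
    assert match_dependency_pattern(rule, sent, mentions) == []
    [rule] = _rules_named(grammar, "hyd-paraphrastic@", "hydrolysis")
    matches = match_dependency_pattern(
        rule, sent, mentions, aux_lexicons=grammar.aux_lexicons
    )
    assert len(matches) == 1
    m = matches[0]
    assert sent.tokens[m.trigger[0]].text == "degradation"
    assert m.bindings["theme"][1].text == "RhoA"
    assert m.bindings["cause"][1].text == "Smurf1"


def test_no_lexicon_token_no_match(grammar, kb):
    from litnet.entities import match_entities
    from litnet.preprocess import segment_document

    from litnet.preprocess import DependencyEdge, Sentence, Token, ROOT

    doc = segment_document("MEK1 sees ERK")
    sent = doc.sentences[0]
    sent.deps = [
        DependencyEdge(1, 0, "nsubj"),
        DependencyEdge(ROOT, 1, "root"),
        DependencyEdge(1, 2, "obj"),
    ]
    mentions = match_entities(sent, kb, grammar=False)
    for rule in _rules_named(grammar, "se-declarative@", None):
        assert match_dependency_pattern(rule, sent, mentions) == []


# path-enumeration oracle ---------------------------------------------------


def oracle_walk(sentence, start, steps, aux):
    """Brute-force: enumerate every token sequence of the right length and
    check each consecutive hop is a matching edge (optional steps branch)."""

    def step_choices(steps):
        # expand optional steps into include/skip combinations
        opts = [(s, (True, False) if s.optional else (True,)) for s in steps]
        for mask in itertools.product(*(c for _s, c in opts)):
            yield [s for (s, _c), used in zip(opts, mask) if used]

    results = set()
    edges = {(e.head, e.dependent, e.label) for e in sentence.deps}
    n = len(sentence.tokens)
    for concrete in step_choices(steps):
        k = len(concrete)
        for seq in itertools.product(range(n), repeat=k):
            path = (start,) + seq
            ok = True
            for (a, b), step in zip(zip(path, path[1:]), concrete):
                if step.down:
                    hop_ok = any((a, b, lbl) in edges for lbl in step.labels)
                else:
                    hop_ok = any((b, a, lbl) in edges for lbl in step.labels)
                if hop_ok and step.gate is not None:
                    lex = aux.get(step.gate)
                    t = sentence.tokens[b]
                    hop_ok = lex is not None and lex.matches(t.text, t.lemma, t.pos)
                if not hop_ok:
                    ok = False
                    break
            if ok:
                results.add(path[-1])
    return results


def test_dependency_matcher_equals_path_oracle(grammar, corpus):
    from litnet.grammar.engine import _walk_path

    # every distinct argument/forbid path in the shipped grammar
    paths = {}
    for rule in grammar.rules:
        if rule.dialect != "syntax":
            continue
        for spec in rule.arg_specs:
            paths[spec.path] = True
        for f in rule.forbid:
            paths[f] = True
    assert len(paths) >= 20

    sentences = []
    for fx in corpus[:: max(1, len(corpus) // 14)]:
        sent = fx.document.sentences[0]
        if len(sent.tokens) <= 25:
            sentences.append((fx.name, sent))

    checked = 0
    for name, sent in sentences:
        for path in paths:
            for start in range(len(sent.tokens)):
                got = _walk_path(sent, start, path, grammar.aux_lexicons)
                want = oracle_walk(sent, start, path, grammar.aux_lexicons)
                assert got == want, (name, path, start)
                checked += 1
    assert checked > 0


def test_match_set_is_order_independent(grammar, corpus, kb):
    from litnet.entities import match_entities

    fx = fixture_by_name(corpus, "vb-declarative")
    sent = fx.document.sentences[0]
    mentions = match_entities(sent, kb, grammar=grammar)
    a = grammar.match_sentence(sent, mentions)
    rules_reversed = list(reversed(grammar.rules))
    saved = grammar.rules
    try:
        grammar.rules = rules_reversed
        b = grammar.match_sentence(sent, mentions)
    finally:
        grammar.rules = saved
    key = lambda m: (m.rule, m.binding_key())  # noqa: E731
    assert sorted(key(m) for m in a) == sorted(key(m) for m in b)


# ---------------------------------------------------------------- surface matching


def _surface_rule(grammar, name):
    [rule] = [r for r in grammar.rules if r.name == name]
    return rule


def test_surface_mutant_match(grammar):
    from litnet.preprocess import segment_document

    sent = segment_document("the K134A mutant").sentences[0]
    rule = _surface_rule(grammar, "mut-variant-mutant")
    matches = match_surface_pattern(rule, sent)
    assert len(matches) == 1
    assert matches[0].bindings["variant"] == (1, 2)


def test_surface_phospho_prefix(grammar, kb):
    from litnet.entities import match_entities
    from litnet.preprocess import segment_document

    sent = segment_document("phospho-ERK was detected").sentences[0]
    mentions = match_entities(sent, kb, grammar=False)
    rule = _surface_rule(grammar, "mod-ptm-prefix")
    matches = match_surface_pattern(rule, sent, mentions)
    assert len(matches) == 1
    kind, target = matches[0].bindings["target"]
    assert kind == "mention" and target.text == "ERK"


def test_surface_empty_sentence(grammar):
    from litnet.preprocess import Sentence

    rule = _surface_rule(grammar, "mut-variant-mutant")
    assert match_surface_pattern(rule, Sentence(tokens=[], text="")) == []


def test_surface_no_overlap_within_rule(grammar):
    from litnet.preprocess import segment_document

    sent = segment_document("K134A mutant K134A mutant").sentences[0]
    rule = _surface_rule(grammar, "mut-variant-mutant")
    matches = match_surface_pattern(rule, sent)
    assert len(matches) == 2
    spans = [(m.trigger[0], m.trigger[1]) for m in matches]
    assert spans == sorted(spans)


def test_surface_generic_entity(grammar):
    from litnet.preprocess import segment_document

    sent = segment_document("this protein binds stuff").sentences[0]
    mentions = grammar.entity_mentions(sent)
    generics = [m for m in mentions if m.generic]
    assert len(generics) == 1
    assert generics[0].span == (0, 2)


def test_entity_rule_site_beats_gene_pattern(grammar, kb):
    from litnet.entities import match_entities
    from litnet.preprocess import segment_document

    sent = segment_document("Ser37 and S83").sentences[0]
    got = match_entities(sent, kb, grammar=grammar)
    types = {m.text: m.entity_type for m in got}
    assert types["Ser37"] == "site"
    assert types["S83"] == "site"
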