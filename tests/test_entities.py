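import io
import itertools

import pytest

from litnet.entities import (
    DEFAULT_KB_PRIORITY,
    EntityMention,
    KBLoadError,
    Modification,
    attach_states,
    dictionary_candidates,
    ground,
    load_kb,
    match_entities,
    select_non_overlapping,
)
from litnet.fixtures import builtin_kb_tsv
from litnet.preprocess import segment_document

KB_TSV = (
    "uniprot\tQ02750\tMAP2K1\tMEK1|MAP kinase kinase 1\tgene_or_gene_product\n"
    "uniprot\tP28482\tERK\tMAPK1\tgene_or_gene_product\n"
    "uniprot\tQ16539\tMAPK14\tp38\tgene_or_gene_product\n"
    "interpro\tIPR008352\tp38 family\tp38\tfamily\n"
    "chebi\tCHEBI:17489\tcAMP\tcyclic AMP\tsimple_chemical\n"
    "hmdb\tHMDB0000058\tcAMP\t\tsimple_chemical\n"
    "uniprot\tQ9XYZ1\tEHR\t\tgene_or_gene_product\n"
    "uniprot\tP16104\tH2AX\t\tgene_or_gene_product\n"
)


@pytest.fixture()
def small_kb():
    return load_kb(io.StringIO(KB_TSV))


def _sentence(text):
    return segment_document(text).sentences[0]


# ---------------------------------------------------------------- load_kb


def test_load_kb_lookup_synonym(small_kb):
    hits = small_kb.lookup("MEK1")
    assert [h.identifier for h in hits] == ["Q02750"]


def test_load_kb_empty():
    kb = load_kb(io.StringIO(""))
    assert len(kb) == 0


def test_load_kb_shared_synonym_returns_both(small_kb):
    hits = small_kb.lookup("p38")
    # oracle: linear scan over all entries
    expected = {
        (e.namespace, e.identifier)
        for e in small_kb.entries
        if "p38" in e.names()
    }
    assert {(h.namespace, h.identifier) for h in hits} == expected
    assert len(hits) == 2


def test_load_kb_conflicting_type_is_error():
    rows = (
        "uniprot\tX1\tFoo\t\tgene_or_gene_product\n"
        "uniprot\tX1\tFoo\t\tfamily\n"
    )
    with pytest.raises(KBLoadError):
        load_kb(io.StringIO(rows))


def test_load_kb_bad_columns_names_line():
    with pytest.raises(KBLoadError, match="line 1"):
        load_kb(io.StringIO("too\tfew\n"))


def test_load_kb_synonyms_deduplicated_case_insensitively():
    kb = load_kb(io.StringIO("uniprot\tX1\tFoo\tBAR|bar|Bar\tgene_or_gene_product\n"))
    assert kb.entries[0].synonyms == ("BAR",)


# ---------------------------------------------------------------- matching


def brute_force_ngram_oracle(sentence, kb):
    """Enumerate every token n-gram against the index, then apply
    longest/leftmost selection."""
    n = len(sentence.tokens)
    cands = []
    for i, j in itertools.combinations(range(n + 1), 2):
        text = sentence.span_text(i, j)
        if kb.lookup(text):
            cands.append((i, j, text))
    chosen = []
    for i, j, text in sorted(cands, key=lambda c: (-(c[1] - c[0]), c[0])):
        if all(j <= a or i >= b for a, b, _t in chosen):
            chosen.append((i, j, text))
    return sorted((i, j) for i, j, _t in chosen)


def test_match_entities_two_mentions(small_kb):
    sent = _sentence("MEK1 phosphorylates ERK")
    got = match_entities(sent, small_kb, grammar=False)
    assert [(m.start, m.end) for m in got] == brute_force_ngram_oracle(sent, small_kb)
    assert len(got) == 2


def test_match_entities_no_hits(small_kb):
    sent = _sentence("nothing relevant here")
    assert match_entities(sent, small_kb, grammar=False) == []


def test_match_entities_wild_type_context(small_kb):
    sent = _sentence("wild type EHR")
    got = match_entities(sent, small_kb, grammar=False)
    assert [m.text for m in got] == ["EHR"]


@pytest.mark.parametrize(
    "text",
    [
        "MEK1 binds MAP kinase kinase 1",
        "the p38 pathway and MAPK14 and cyclic AMP",
        "ERK ERK MEK1",
        "cAMP and EHR bind H2AX-K134A",
    ],
)
def test_ngram_oracle_equivalence(small_kb, text):
    sent = _sentence(text)
    assert len(sent.tokens) <= 30
    got = match_entities(sent, small_kb, grammar=False)
    assert [(m.start, m.end) for m in got] == brute_force_ngram_oracle(sent, small_kb)


def test_match_entities_soundness(small_kb):
    sent = _sentence("MAP kinase kinase 1 activates cyclic AMP signaling")
    for m in match_entities(sent, small_kb, grammar=False):
        assert small_kb.lookup(m.text)


def test_pattern_entities_via_grammar(small_kb):
    sent = _sentence("MEK1 phosphorylates ERK at Ser37 in the nucleus")
    got = match_entities(sent, small_kb)
    by_text = {m.text: m.entity_type for m in got}
    assert by_text["Ser37"] == "site"
    assert by_text["nucleus"] == "cellular_component"


def test_longest_match_wins():
    kb = load_kb(io.StringIO(
        "uniprot\tA1\tMAP\t\tgene_or_gene_product\n"
        "uniprot\tA2\tMAP kinase\t\tgene_or_gene_product\n"
    ))
    sent = _sentence("MAP kinase signaling")
    got = match_entities(sent, kb, grammar=False)
    assert [m.text for m in got] == ["MAP kinase"]


def test_select_non_overlapping_leftmost_tie():
    mk = lambda i, j: EntityMention("d", 0, i, j, "x", "gene_or_gene_product")  # noqa: E731
    out = select_non_overlapping([mk(2, 4), mk(1, 3)])
    assert [(m.start, m.end) for m in out] == [(1, 3)]


# ---------------------------------------------------------------- grounding


def test_ground_mek1(small_kb):
    sent = _sentence("MEK1")
    m = match_entities(sent, small_kb, grammar=False)[0]
    ground(m, small_kb)
    assert m.groundings[0] == ("uniprot", "Q02750")


def test_ground_pattern_mention_gets_local_id(small_kb):
    m = EntityMention("d", 0, 0, 1, "Ser37", "site")
    ground(m, small_kb)
    assert m.groundings[0][0] == "uaz"


def test_ground_chebi_before_hmdb(small_kb):
    m = EntityMention("d", 0, 0, 1, "cAMP", "simple_chemical")
    ground(m, small_kb)
    # oracle: priority-sorted brute-force lookup
    expected = sorted(
        {
            (e.namespace, e.identifier)
            for e in small_kb.entries
            if "cAMP" in e.names() and e.entity_type == "simple_chemical"
        },
        key=lambda g: DEFAULT_KB_PRIORITY.index(g[0]),
    )
    assert m.groundings == expected
    assert m.groundings[0][0] == "chebi"


def test_ground_idempotent(small_kb):
    m = EntityMention("d", 0, 0, 1, "MEK1", "gene_or_gene_product")
    ground(m, small_kb)
    before = list(m.groundings)
    ground(m, small_kb)
    assert m.groundings == before


def test_ground_stable_under_synonym_permutation():
    base = ["MEK1", "MAP kinase kinase 1", "MAPKK1"]
    results = []
    for perm in itertools.permutations(base):
        kb = load_kb(io.StringIO(
            f"uniprot\tQ02750\tMAP2K1\t{'|'.join(perm)}\tgene_or_gene_product\n"
        ))
        m = EntityMention("d", 0, 0, 1, "MEK1", "gene_or_gene_product")
        ground(m, kb)
        results.append(m.groundings)
    assert all(r == results[0] for r in results)


# ---------------------------------------------------------------- states


def _mentioned(text, kb):
    sent = _sentence(text)
    mentions = match_entities(sent, kb, grammar=False)
    attach_states(sent, mentions)
    return sent, mentions


def test_wild_type(small_kb):
    _s, ms = _mentioned("wild type EHR", small_kb)
    assert Modification("WildType", evidence=(0, 2)) in ms[0].modifications


def test_wt_suffix(small_kb):
    _s, ms = _mentioned("H2AX-WT", small_kb)
    assert any(m.kind == "WildType" for m in ms[0].modifications)


def test_mutant_suffix(small_kb):
    _s, ms = _mentioned("recombinant H2AX-K134A", small_kb)
    mods = ms[0].modifications
    assert any(m.kind == "Mutant" and m.variant == "K134A" for m in mods)


def test_mutant_of_phrase(small_kb):
    _s, ms = _mentioned("the K134A mutant of H2AX", small_kb)
    assert any(
        m.kind == "Mutant" and m.variant == "K134A" for m in ms[0].modifications
    )


def test_phospho_prefix(small_kb):
    _s, ms = _mentioned("phospho-ERK", small_kb)
    assert any(
        m.kind == "PTM" and m.subtype == "phosphorylation"
        for m in ms[0].modifications
    )


def test_participle_ptm(small_kb):
    _s, ms = _mentioned("ubiquitinated H2AX", small_kb)
    assert any(
        m.kind == "PTM" and m.subtype == "ubiquitination"
        for m in ms[0].modifications
    )


def test_bare_mention_no_modifications(small_kb):
    _s, ms = _mentioned("ERK", small_kb)
    assert ms[0].modifications == []


def test_ptm_subtype_validated():
    with pytest.raises(ValueError):
        Modification("PTM", subtype="frobnication")


def test_builtin_kb_tsv_parses():
    kb = load_kb(io.StringIO(builtin_kb_tsv()))
    assert kb.lookup("MEK1")
    assert kb.lookup("LL-37")


def test_mentions_never_overlap(small_kb):
    sent = _sentence("MAP kinase kinase 1 and p38 and cAMP bind MEK1")
    got = match_entities(sent, small_kb)
    for a, b in itertools.combinations(got, 2):
        assert a.end <= b.start or b.end <= a.start


def test_statistical_tagger_loses_on_overlap(small_kb):
    def tagger(sentence):
        return [
            EntityMention("doc", 0, 0, 2, "MEK1 phosphorylates", "gene_or_gene_product"),
            EntityMention("doc", 0, 3, 4, "XYZ99", "gene_or_gene_product"),
        ]

    sent = _sentence("MEK1 phosphorylates ERK XYZ99")
    got = match_entities(sent, small_kb, grammar=False, tagger=tagger)
    texts = [m.text for m in got]
    assert "MEK1" in texts  # rule-based wins the overlap
    assert "MEK1 phosphorylates" not in texts
    assert "XYZ99" in texts  # non-overlapping tagger output is kept
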