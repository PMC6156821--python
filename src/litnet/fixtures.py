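"""Synthetic gold corpus: sentences with hand-built dependency trees.

Every skeleton emits the surface string and its tree together with the
gold annotation, so the rule engine can be tested without a live
parser.  The generator covers each of the ten syntactic variations per
requested event type, plus coordination, polarity, negation and
coreference phenomena; a small set of verbatim sentences with
hand-built trees ships as static fixtures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Sequence

from litnet.entities import EntityMention, KB, KBEntry, Modification
from litnet.events import EventMention
from litnet.grammar.engine import PTM_ADDITIONS, VARIATIONS
from litnet.preprocess import ROOT, Document, DependencyEdge, Sentence, Token, validate_sentence


@dataclass
class GoldAnnotation:
    doc_id: str
    mentions: list[EntityMention] = field(default_factory=list)
    events: list[EventMention] = field(default_factory=list)
    links: list[tuple[tuple[int, int, int], tuple[int, int, int]]] = field(
        default_factory=list
    )  # (sent, start, end) anaphor -> antecedent


@dataclass
class Fixture:
    name: str
    document: Document
    gold: GoldAnnotation
    phenomena: tuple[str, ...] = ()


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------
# sentence building
# ---------------------------------------------------------------------


class SentenceBuilder:
    """Assemble a Sentence from (text, pos, head, label) rows.

    ``head`` indexes rows (-1 for ROOT).  ``glue=True`` attaches a token
    to its predecessor without a space (dash-split names).
    """

    def __init__(self) -> None:
        self.rows: list[tuple[str, str, int, str, str, bool]] = []

    def t(
        self, text: str, pos: str, head: int, label: str,
        lemma: str | None = None, glue: bool = False,
    ) -> int:
        self.rows.append((text, pos, head, label, lemma or text.lower(), glue))
        return len(self.rows) - 1

    def build(self, offset: int = 0) -> Sentence:
        tokens: list[Token] = []
        cursor = offset
        for i, (text, pos, _h, _l, lemma, glue) in enumerate(self.rows):
            if i > 0 and not glue:
                cursor += 1
            tokens.append(Token(i, text, cursor, cursor + len(text), pos, lemma))
            cursor += len(text)
        deps = [
            DependencyEdge(ROOT if h < 0 else h, i, lbl)
            for i, (_t, _p, h, lbl, _lm, _g) in enumerate(self.rows)
        ]
        base = tokens[0].start
        text = ""
        prev = base
        for tok in tokens:
            text += " " * (tok.start - prev) + tok.text
            prev = tok.end
        sent = Sentence(tokens=tokens, deps=deps, text=text)
        validate_sentence(sent)
        return sent


def _doc(doc_id: str, builders: Sequence[SentenceBuilder]) -> Document:
    sentences = []
    offset = 0
    for b in builders:
        s = b.build(offset)
        sentences.append(s)
        offset = s.end + 1
    raw = " ".join(s.text for s in sentences)
    return Document(doc_id=doc_id, sentences=sentences, raw_text=raw)


# ---------------------------------------------------------------------
# built-in KB for fixtures
# ---------------------------------------------------------------------

_KB_ROWS: list[tuple[str, str, str, str, str]] = [
    ("uniprot", "Q02750", "MEK1", "MAP2K1|MAP kinase kinase 1|MEK", "gene_or_gene_product"),
    ("uniprot", "P01112", "Ras", "HRAS", "gene_or_gene_product"),
    ("uniprot", "P28482", "ERK", "MAPK1", "gene_or_gene_product"),
    ("uniprot", "P61586", "RhoA", "", "gene_or_gene_product"),
    ("uniprot", "Q9HCE7", "Smurf1", "", "gene_or_gene_product"),
    ("uniprot", "Q9HAU4", "Smurf2", "", "gene_or_gene_product"),
    ("uniprot", "P01116", "KRAS", "", "gene_or_gene_product"),
    ("uniprot", "P04637", "p53", "TP53", "gene_or_gene_product"),
    ("uniprot", "P21580", "A20", "TNFAIP3", "gene_or_gene_product"),
    ("uniprot", "Q15025", "ABIN", "TNIP1", "gene_or_gene_product"),
    ("uniprot", "P0A9Q9", "Pde2", "", "gene_or_gene_product"),
    ("uniprot", "P02741", "CRP", "", "gene_or_gene_product"),
    ("uniprot", "Q12923", "PTPN13", "", "gene_or_gene_product"),
    ("uniprot", "P98172", "EphrinB1", "EFNB1", "gene_or_gene_product"),
    ("uniprot", "Q13185", "HP1γ", "CBX3", "gene_or_gene_product"),
    ("uniprot", "P16104", "H2AX", "", "gene_or_gene_product"),
    ("uniprot", "P49913", "LL-37", "CAMP peptide", "gene_or_gene_product"),
    ("uniprot", "P08069", "IGF-1R", "IGF1R", "gene_or_gene_product"),
    ("uniprot", "O14641", "Dvl2", "", "gene_or_gene_product"),
    ("uniprot", "P41743", "aPKC", "PRKCI", "gene_or_gene_product"),
    ("uniprot", "O14965", "Aurora A", "AURKA", "gene_or_gene_product"),
    ("uniprot", "P60953", "Cdc42", "", "gene_or_gene_product"),
    ("uniprot", "P24941", "CDK2", "", "gene_or_gene_product"),
    ("uniprot", "P31749", "AKT1", "", "gene_or_gene_product"),
    ("uniprot", "P40763", "STAT3", "", "gene_or_gene_product"),
    ("uniprot", "O60674", "JAK2", "", "gene_or_gene_product"),
    ("interpro", "IPR000719", "kinase domain", "", "family"),
    ("interpro", "IPR003527", "MAPK", "MAP kinase", "family"),
    ("chebi", "CHEBI:17489", "cAMP", "cyclic AMP", "simple_chemical"),
    ("hmdb", "HMDB0000058", "cAMP", "", "simple_chemical"),
    ("chebi", "CHEBI:15422", "ATP", "", "simple_chemical"),
]


def builtin_kb() -> KB:
    kb = KB()
    for ns, ident, canonical, syns, etype in _KB_ROWS:
        synonyms = tuple(s for s in syns.split("|") if s)
        kb.add(KBEntry(ns, ident, canonical, synonyms, etype))
    return kb


def builtin_kb_tsv() -> str:
    return "\n".join("\t".join(r) for r in _KB_ROWS) + "\n"


#: entity names used by the generator (single token, in the KB)
_PROTEINS = ["MEK1", "ERK", "RhoA", "Smurf1", "KRAS", "p53", "CDK2", "AKT1",
             "STAT3", "JAK2", "Cdc42", "PTPN13", "EphrinB1"]


def _forms(label: str) -> dict[str, str]:
    if label == "hydrolysis":
        return {"v3": "degrades", "part": "degraded", "noun": "degradation",
                "base": "degrade"}
    if label == "translocation":
        return {"v3": "transports", "part": "transported", "noun": "translocation",
                "base": "transport"}
    stem = label[:-3] + "e"  # phosphorylation -> phosphorylate
    return {"v3": stem + "s", "part": stem[:-1] + "ed", "noun": label, "base": stem}


# ---------------------------------------------------------------------
# gold helpers
# ---------------------------------------------------------------------


def _mention(doc_id: str, si: int, sent: Sentence, i: int, j: int,
             etype: str = "gene_or_gene_product", **kw) -> EntityMention:
    return EntityMention(
        doc_id=doc_id, sent_index=si, start=i, end=j,
        text=sent.span_text(i, j), entity_type=etype, **kw,
    )


def _simple(doc_id: str, si: int, sent: Sentence, label: str, trig: int,
            theme: EntityMention, site: EntityMention | None = None,
            negated: bool = False, extra: dict | None = None) -> EventMention:
    args: dict[str, list] = {"theme": [theme]}
    if site is not None:
        args["site"] = [site]
    if extra:
        for k, v in extra.items():
            args[k] = list(v)
    return EventMention(
        doc_id=doc_id, sent_index=si, label=label, trigger=(trig, trig + 1),
        trigger_text=sent.tokens[trig].text, arguments=args, negated=negated,
    )


def _binding(doc_id: str, si: int, sent: Sentence, trig: int,
             a: EntityMention, b: EntityMention) -> EventMention:
    themes = sorted([a, b], key=lambda m: m.start)
    return EventMention(
        doc_id=doc_id, sent_index=si, label="binding", trigger=(trig, trig + 1),
        trigger_text=sent.tokens[trig].text, arguments={"theme": themes},
    )


def _reg(doc_id: str, si: int, sent: Sentence, sign: int, trig: int,
         controller, controlled, negated: bool = False) -> EventMention:
    if isinstance(controlled, EventMention):
        label = "positive_regulation" if sign > 0 else "negative_regulation"
    else:
        label = "positive_activation" if sign > 0 else "negative_activation"
    return EventMention(
        doc_id=doc_id, sent_index=si, label=label, trigger=(trig, trig + 1),
        trigger_text=sent.tokens[trig].text,
        arguments={"controller": [controller], "controlled": [controlled]},
        sign=sign, negated=negated,
    )


# ---------------------------------------------------------------------
# variation skeletons for single-theme simple events
# ---------------------------------------------------------------------
# Each returns (builder, gold_fn) where gold_fn(doc_id, si, sent) gives
# (mentions, events); token indices are fixed by construction.


def _sk_declarative(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t(cause, "NNP", 1, "nsubj")
    b.t(f["v3"], "VBZ", -1, "root", lemma=f["base"])
    b.t(theme, "NNP", 1, "obj")
    b.t(".", ".", 1, "punct")

    def gold(doc_id, si, sent):
        c = _mention(doc_id, si, sent, 0, 1)
        t = _mention(doc_id, si, sent, 2, 3)
        ev = _simple(doc_id, si, sent, label, 1, t)
        return [c, t], [ev, _reg(doc_id, si, sent, +1, 1, c, ev)]

    return b, gold


def _sk_passive(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t(theme, "NNP", 2, "nsubjpass")
    b.t("is", "VBZ", 2, "auxpass", lemma="be")
    b.t(f["part"], "VBN", -1, "root", lemma=f["base"])
    b.t("by", "IN", 4, "case")
    b.t(cause, "NNP", 2, "nmod_by")
    b.t(".", ".", 2, "punct")

    def gold(doc_id, si, sent):
        t = _mention(doc_id, si, sent, 0, 1)
        c = _mention(doc_id, si, sent, 4, 5)
        ev = _simple(doc_id, si, sent, label, 2, t)
        return [t, c], [ev, _reg(doc_id, si, sent, +1, 2, c, ev)]

    return b, gold


def _sk_prep_nominalization(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t("The", "DT", 1, "det", lemma="the")
    b.t(f["noun"], "NN", 6, "nsubj", lemma=f["noun"])
    b.t("of", "IN", 3, "case")
    b.t(theme, "NNP", 1, "nmod_of")
    b.t("by", "IN", 5, "case")
    b.t(cause, "NNP", 1, "nmod_by")
    b.t("increased", "VBD", -1, "root", lemma="increase")
    b.t(".", ".", 6, "punct")

    def gold(doc_id, si, sent):
        t = _mention(doc_id, si, sent, 3, 4)
        c = _mention(doc_id, si, sent, 5, 6)
        ev = _simple(doc_id, si, sent, label, 1, t)
        return [t, c], [ev, _reg(doc_id, si, sent, +1, 1, c, ev)]

    return b, gold


def _sk_obj_nominalization(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t(theme, "NNP", 1, "compound")
    b.t(f["noun"], "NN", 4, "nsubj", lemma=f["noun"])
    b.t("by", "IN", 3, "case")
    b.t(cause, "NNP", 1, "nmod_by")
    b.t("increased", "VBD", -1, "root", lemma="increase")
    b.t(".", ".", 4, "punct")

    def gold(doc_id, si, sent):
        t = _mention(doc_id, si, sent, 0, 1)
        c = _mention(doc_id, si, sent, 3, 4)
        ev = _simple(doc_id, si, sent, label, 1, t)
        return [t, c], [ev, _reg(doc_id, si, sent, +1, 1, c, ev)]

    return b, gold


def _sk_subj_nominalization(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t(cause, "NNP", 1, "compound")
    b.t(f["noun"], "NN", 4, "nsubj", lemma=f["noun"])
    b.t("of", "IN", 3, "case")
    b.t(theme, "NNP", 1, "nmod_of")
    b.t("increased", "VBD", -1, "root", lemma="increase")
    b.t(".", ".", 4, "punct")

    def gold(doc_id, si, sent):
        c = _mention(doc_id, si, sent, 0, 1)
        t = _mention(doc_id, si, sent, 3, 4)
        ev = _simple(doc_id, si, sent, label, 1, t)
        return [c, t], [ev, _reg(doc_id, si, sent, +1, 1, c, ev)]

    return b, gold


def _sk_subj_relclause(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t("We", "PRP", 1, "nsubj", lemma="we")
    b.t("studied", "VBD", -1, "root", lemma="study")
    b.t(cause, "NNP", 1, "obj")
    b.t(",", ",", 2, "punct")
    b.t("which", "WDT", 5, "nsubj", lemma="which")
    b.t(f["v3"], "VBZ", 2, "acl:relcl", lemma=f["base"])
    b.t(theme, "NNP", 5, "obj")
    b.t(".", ".", 1, "punct")

    def gold(doc_id, si, sent):
        c = _mention(doc_id, si, sent, 2, 3)
        t = _mention(doc_id, si, sent, 6, 7)
        ev = _simple(doc_id, si, sent, label, 5, t)
        return [c, t], [ev, _reg(doc_id, si, sent, +1, 5, c, ev)]

    return b, gold


def _sk_obj_relclause(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t("We", "PRP", 1, "nsubj", lemma="we")
    b.t("studied", "VBD", -1, "root", lemma="study")
    b.t(theme, "NNP", 1, "obj")
    b.t(",", ",", 2, "punct")
    b.t("which", "WDT", 6, "nsubjpass", lemma="which")
    b.t("is", "VBZ", 6, "auxpass", lemma="be")
    b.t(f["part"], "VBN", 2, "acl:relcl", lemma=f["base"])
    b.t("by", "IN", 8, "case")
    b.t(cause, "NNP", 6, "nmod_by")
    b.t(".", ".", 1, "punct")

    def gold(doc_id, si, sent):
        t = _mention(doc_id, si, sent, 2, 3)
        c = _mention(doc_id, si, sent, 8, 9)
        ev = _simple(doc_id, si, sent, label, 6, t)
        return [t, c], [ev, _reg(doc_id, si, sent, +1, 6, c, ev)]

    return b, gold


def _sk_subj_apposition(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t("A", "DT", 2, "det", lemma="a")
    b.t("novel", "JJ", 2, "amod")
    b.t("ligase", "NN", 5, "nsubj")
    b.t(",", ",", 2, "punct")
    b.t(cause, "NNP", 2, "appos")
    b.t(f["v3"], "VBZ", -1, "root", lemma=f["base"])
    b.t(theme, "NNP", 5, "obj")
    b.t(".", ".", 5, "punct")

    def gold(doc_id, si, sent):
        c = _mention(doc_id, si, sent, 4, 5)
        t = _mention(doc_id, si, sent, 6, 7)
        ev = _simple(doc_id, si, sent, label, 5, t)
        return [c, t], [ev, _reg(doc_id, si, sent, +1, 5, c, ev)]

    return b, gold


def _sk_obj_apposition(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t(cause, "NNP", 1, "nsubj")
    b.t(f["v3"], "VBZ", -1, "root", lemma=f["base"])
    b.t("a", "DT", 4, "det")
    b.t("novel", "JJ", 4, "amod")
    b.t("substrate", "NN", 1, "obj")
    b.t(",", ",", 4, "punct")
    b.t(theme, "NNP", 4, "appos")
    b.t(".", ".", 1, "punct")

    def gold(doc_id, si, sent):
        c = _mention(doc_id, si, sent, 0, 1)
        t = _mention(doc_id, si, sent, 6, 7)
        ev = _simple(doc_id, si, sent, label, 1, t)
        return [c, t], [ev, _reg(doc_id, si, sent, +1, 1, c, ev)]

    return b, gold


def _sk_paraphrastic_causative(label, cause, theme):
    f = _forms(label)
    b = SentenceBuilder()
    b.t(cause, "NNP", 1, "nsubj")
    b.t("causes", "VBZ", -1, "root", lemma="cause")
    b.t("the", "DT", 3, "det")
    b.t(f["noun"], "NN", 1, "obj", lemma=f["noun"])
    b.t("of", "IN", 5, "case")
    b.t(theme, "NNP", 3, "nmod_of")
    b.t(".", ".", 1, "punct")

    def gold(doc_id, si, sent):
        c = _mention(doc_id, si, sent, 0, 1)
        t = _mention(doc_id, si, sent, 5, 6)
        ev = _simple(doc_id, si, sent, label, 3, t)
        return [c, t], [ev, _reg(doc_id, si, sent, +1, 3, c, ev)]

    return b, gold


SKELETONS: dict[str, Callable] = {
    "declarative": _sk_declarative,
    "passive": _sk_passive,
    "prepositional_nominalization": _sk_prep_nominalization,
    "object_nominalization": _sk_obj_nominalization,
    "subject_nominalization": _sk_subj_nominalization,
    "subject_relative_clause": _sk_subj_relclause,
    "object_relative_clause": _sk_obj_relclause,
    "subject_apposition": _sk_subj_apposition,
    "object_apposition": _sk_obj_apposition,
    "paraphrastic_causative": _sk_paraphrastic_causative,
}


# ---------------------------------------------------------------------
# phenomenon skeletons
# ---------------------------------------------------------------------


def _fx_combination(doc_id: str, label: str, cause: str, theme: str, target: str) -> Fixture:
    """Appositive subject relative plus passivization plus an activation."""
    f = _forms(label)
    b = SentenceBuilder()
    b.t(cause, "NNP", 9, "nsubj")
    b.t(",", ",", 0, "punct")
    b.t("which", "WDT", 5, "nsubjpass", lemma="which")
    b.t("has", "VBZ", 5, "aux", lemma="have")
    b.t("been", "VBN", 5, "auxpass", lemma="be")
    b.t("found", "VBN", 0, "acl:relcl", lemma="find")
    b.t("to", "TO", 7, "mark")
    b.t(f["base"], "VB", 5, "xcomp", lemma=f["base"])
    b.t(theme, "NNP", 7, "obj")
    b.t("activates", "VBZ", -1, "root", lemma="activate")
    b.t(target, "NNP", 9, "obj")
    b.t(".", ".", 9, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 0, 1)
    t = _mention(doc_id, 0, sent, 8, 9)
    m = _mention(doc_id, 0, sent, 10, 11)
    ev = _simple(doc_id, 0, sent, label, 7, t)
    gold = GoldAnnotation(
        doc_id,
        mentions=[c, t, m],
        events=[ev, _reg(doc_id, 0, sent, +1, 7, c, ev),
                _reg(doc_id, 0, sent, +1, 9, c, m)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("combination",))


def _fx_coordination(doc_id: str, c1: str, c2: str, theme: str) -> Fixture:
    """'C1 and C2 degrade and ubiquitinate T.' -> 2 events x 2 regulations."""
    b = SentenceBuilder()
    b.t(c1, "NNP", 3, "nsubj")
    b.t("and", "CC", 2, "cc")
    b.t(c2, "NNP", 0, "conj")
    b.t("degrade", "VBP", -1, "root", lemma="degrade")
    b.t("and", "CC", 5, "cc")
    b.t("ubiquitinate", "VBP", 3, "conj", lemma="ubiquitinate")
    b.t(theme, "NNP", 3, "obj")
    b.t(".", ".", 3, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    m1 = _mention(doc_id, 0, sent, 0, 1)
    m2 = _mention(doc_id, 0, sent, 2, 3)
    t = _mention(doc_id, 0, sent, 6, 7)
    hyd = _simple(doc_id, 0, sent, "hydrolysis", 3, t)
    ubi = _simple(doc_id, 0, sent, "ubiquitination", 5, t)
    gold = GoldAnnotation(
        doc_id,
        mentions=[m1, m2, t],
        events=[
            hyd, ubi,
            _reg(doc_id, 0, sent, +1, 3, m1, hyd),
            _reg(doc_id, 0, sent, +1, 3, m2, hyd),
            _reg(doc_id, 0, sent, +1, 5, m1, ubi),
            _reg(doc_id, 0, sent, +1, 5, m2, ubi),
        ],
    )
    return Fixture(doc_id, doc, gold, phenomena=("coordination",))


def _fx_polarity(doc_id: str, cause: str, theme: str, label: str) -> Fixture:
    """'Decreased C expression enhances the <noun> of T.'"""
    f = _forms(label)
    b = SentenceBuilder()
    b.t("Decreased", "JJ", 2, "amod", lemma="decreased")
    b.t(cause, "NNP", 2, "compound")
    b.t("expression", "NN", 3, "nsubj")
    b.t("enhances", "VBZ", -1, "root", lemma="enhance")
    b.t("the", "DT", 5, "det")
    b.t(f["noun"], "NN", 3, "obj", lemma=f["noun"])
    b.t("of", "IN", 7, "case")
    b.t(theme, "NNP", 5, "nmod_of")
    b.t(".", ".", 3, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 1, 2)
    t = _mention(doc_id, 0, sent, 7, 8)
    ev = _simple(doc_id, 0, sent, label, 5, t)
    gold = GoldAnnotation(
        doc_id, mentions=[c, t],
        events=[ev, _reg(doc_id, 0, sent, -1, 3, c, ev)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("polarity",))


def _fx_negation(doc_id: str, cause: str, theme: str, label: str) -> Fixture:
    """'C does not <verb> T.'"""
    f = _forms(label)
    b = SentenceBuilder()
    b.t(cause, "NNP", 3, "nsubj")
    b.t("does", "VBZ", 3, "aux", lemma="do")
    b.t("not", "RB", 3, "neg", lemma="not")
    b.t(f["base"], "VB", -1, "root", lemma=f["base"])
    b.t(theme, "NNP", 3, "obj")
    b.t(".", ".", 3, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 0, 1)
    t = _mention(doc_id, 0, sent, 4, 5)
    ev = _simple(doc_id, 0, sent, label, 3, t, negated=True)
    gold = GoldAnnotation(
        doc_id, mentions=[c, t],
        events=[ev, _reg(doc_id, 0, sent, +1, 3, c, ev, negated=True)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("negation",))


def _fx_binding_declarative(doc_id: str, a: str, bname: str) -> Fixture:
    b = SentenceBuilder()
    b.t(a, "NNP", 1, "nsubj")
    b.t("binds", "VBZ", -1, "root", lemma="bind")
    b.t("to", "IN", 3, "case")
    b.t(bname, "NNP", 1, "nmod_to")
    b.t(".", ".", 1, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    m1 = _mention(doc_id, 0, sent, 0, 1)
    m2 = _mention(doc_id, 0, sent, 3, 4)
    gold = GoldAnnotation(
        doc_id, mentions=[m1, m2],
        events=[_binding(doc_id, 0, sent, 1, m1, m2)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("binding",))


def _fx_translocation(doc_id: str, cause: str, theme: str) -> Fixture:
    b = SentenceBuilder()
    b.t(cause, "NNP", 1, "nsubj")
    b.t("transports", "VBZ", -1, "root", lemma="transport")
    b.t(theme, "NNP", 1, "obj")
    b.t("from", "IN", 5, "case")
    b.t("the", "DT", 5, "det")
    b.t("cytoplasm", "NN", 1, "nmod_from")
    b.t("to", "IN", 8, "case")
    b.t("the", "DT", 8, "det")
    b.t("nucleus", "NN", 1, "nmod_to")
    b.t(".", ".", 1, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 0, 1)
    t = _mention(doc_id, 0, sent, 2, 3)
    src = _mention(doc_id, 0, sent, 5, 6, etype="cellular_component")
    dst = _mention(doc_id, 0, sent, 8, 9, etype="cellular_component")
    ev = _simple(doc_id, 0, sent, "translocation", 1, t,
                 extra={"source": [src], "destination": [dst]})
    gold = GoldAnnotation(
        doc_id, mentions=[c, t, src, dst],
        events=[ev, _reg(doc_id, 0, sent, +1, 1, c, ev)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("translocation",))


def _fx_site(doc_id: str, cause: str, theme: str, site: str) -> Fixture:
    b = SentenceBuilder()
    b.t(cause, "NNP", 1, "nsubj")
    b.t("phosphorylates", "VBZ", -1, "root", lemma="phosphorylate")
    b.t(theme, "NNP", 1, "obj")
    b.t("at", "IN", 4, "case")
    b.t(site, "NNP", 1, "nmod_at")
    b.t(".", ".", 1, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 0, 1)
    t = _mention(doc_id, 0, sent, 2, 3)
    s = _mention(doc_id, 0, sent, 4, 5, etype="site")
    ev = _simple(doc_id, 0, sent, "phosphorylation", 1, t, site=s)
    gold = GoldAnnotation(
        doc_id, mentions=[c, t, s],
        events=[ev, _reg(doc_id, 0, sent, +1, 1, c, ev)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("site",))


def _fx_coref_entity(doc_id: str, name: str, label: str) -> Fixture:
    """S1 introduces the protein; S2 refers to it as 'this protein'."""
    f = _forms(label)
    b1 = SentenceBuilder()
    b1.t("We", "PRP", 1, "nsubj", lemma="we")
    b1.t("studied", "VBD", -1, "root", lemma="study")
    b1.t(name, "NNP", 1, "obj")
    b1.t(".", ".", 1, "punct")
    b2 = SentenceBuilder()
    b2.t("The", "DT", 1, "det", lemma="the")
    b2.t(f["noun"], "NN", 5, "nsubj", lemma=f["noun"])
    b2.t("of", "IN", 4, "case")
    b2.t("this", "DT", 4, "det", lemma="this")
    b2.t("protein", "NN", 1, "nmod_of")
    b2.t("increased", "VBD", -1, "root", lemma="increase")
    b2.t(".", ".", 5, "punct")
    doc = _doc(doc_id, [b1, b2])
    s1, s2 = doc.sentences
    m = _mention(doc_id, 0, s1, 2, 3)
    alias = _mention(doc_id, 1, s2, 4, 5)
    alias.text = name
    ev = _simple(doc_id, 1, s2, label, 1, alias)
    ev.coref = True
    gold = GoldAnnotation(
        doc_id, mentions=[m], events=[ev],
        links=[((1, 4, 5), (0, 2, 3))],
    )
    return Fixture(doc_id, doc, gold, phenomena=("coref",))


# ---------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------

DEFAULT_CONFIG = {
    "variations": list(VARIATIONS),
    "events": list(PTM_ADDITIONS) + ["dephosphorylation", "deubiquitination",
                                     "hydrolysis"],
    "n_per_variation": 1,
    "phenomena": ["coordination", "polarity", "negation", "binding",
                  "translocation", "site", "combination", "coref"],
}

#: variations each event label's shipped grammar category claims to cover
#: in isolation (hydrolysis has no standalone subject-nominalization or
#: apposition templates; those shapes reach it only via coordination)
_HYDROLYSIS_VARIATIONS = frozenset(
    {"declarative", "passive", "prepositional_nominalization",
     "object_nominalization", "subject_relative_clause",
     "object_relative_clause", "paraphrastic_causative"}
)


def _covered(variation: str, label: str) -> bool:
    if label == "hydrolysis":
        return variation in _HYDROLYSIS_VARIATIONS
    return True


def generate_fixture_corpus(
    config: dict | None = None, seed: int = 7
) -> list[Fixture]:
    """Deterministically instantiate the fixture corpus.

    Unknown variation names raise :class:`ConfigError`; identical
    (config, seed) pairs produce identical corpora.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    rng = random.Random(seed)
    fixtures: list[Fixture] = []
    counter = 0

    for variation in cfg["variations"]:
        if variation not in SKELETONS:
            raise ConfigError(f"unknown variation {variation!r}")
        for label in cfg["events"]:
            if not _covered(variation, label):
                continue
            for _ in range(int(cfg["n_per_variation"])):
                cause, theme = rng.sample(_PROTEINS, 2)
                builder, gold_fn = SKELETONS[variation](label, cause, theme)
                doc_id = f"gen{counter:04d}-{variation}-{label}"
                counter += 1
                doc = _doc(doc_id, [builder])
                sent = doc.sentences[0]
                mentions, events = gold_fn(doc_id, 0, sent)
                fixtures.append(
                    Fixture(doc_id, doc, GoldAnnotation(doc_id, mentions, events),
                            phenomena=(variation,))
                )

    phen = set(cfg.get("phenomena", ()))
    if "coordination" in phen:
        fixtures.append(_fx_coordination("gen-coordination", "Smurf1", "Smurf2", "RhoA"))
    if "polarity" in phen:
        c, t = rng.sample(_PROTEINS, 2)
        fixtures.append(_fx_polarity("gen-polarity", c, t, "phosphorylation"))
    if "negation" in phen:
        c, t = rng.sample(_PROTEINS, 2)
        fixtures.append(_fx_negation("gen-negation", c, t, "ubiquitination"))
    if "binding" in phen:
        fixtures.append(_fx_binding_declarative("gen-binding", "A20", "ABIN"))
    if "translocation" in phen:
        c, t = rng.sample(_PROTEINS, 2)
        fixtures.append(_fx_translocation("gen-translocation", c, t))
    if "site" in phen:
        c, t = rng.sample(_PROTEINS, 2)
        fixtures.append(_fx_site("gen-site", c, t, "Ser37"))
    if "combination" in phen:
        fixtures.append(
            _fx_combination("gen-combination", "hydrolysis", "Pde2", "cAMP", "MEK1")
        )
    if "coref" in phen:
        name = rng.choice(_PROTEINS)
        fixtures.append(_fx_coref_entity("gen-coref", name, "phosphorylation"))
    return fixtures


# ---------------------------------------------------------------------
# static hand-annotated fixtures
# ---------------------------------------------------------------------


def _smurf_gold(doc_id, sent, ubi_trig, hyd_trig, theme_span, cause_spans):
    t = _mention(doc_id, 0, sent, *theme_span)
    causes = [_mention(doc_id, 0, sent, *cs) for cs in cause_spans]
    ubi = _simple(doc_id, 0, sent, "ubiquitination", ubi_trig, t)
    hyd = _simple(doc_id, 0, sent, "hydrolysis", hyd_trig, t)
    events = [ubi, hyd]
    for c in causes:
        events.append(_reg(doc_id, 0, sent, +1, ubi_trig, c, ubi))
        events.append(_reg(doc_id, 0, sent, +1, hyd_trig, c, hyd))
    return GoldAnnotation(doc_id, mentions=[t] + causes, events=events)


def _vb_declarative() -> Fixture:
    fx = _fx_coordination("vb-declarative", "Smurf1", "Smurf2", "RhoA")
    return Fixture(fx.name, fx.document, fx.gold, phenomena=("declarative",))


def _vb_passive() -> Fixture:
    doc_id = "vb-passive"
    b = SentenceBuilder()
    b.t("RhoA", "NNP", 2, "nsubjpass")
    b.t("is", "VBZ", 2, "auxpass", lemma="be")
    b.t("ubiquitinated", "VBN", -1, "root", lemma="ubiquitinate")
    b.t("and", "CC", 4, "cc")
    b.t("degraded", "VBN", 2, "conj", lemma="degrade")
    b.t("by", "IN", 6, "case")
    b.t("Smurf1", "NNP", 2, "nmod_by")
    b.t("and", "CC", 8, "cc")
    b.t("Smurf2", "NNP", 6, "conj")
    b.t(".", ".", 2, "punct")
    doc = _doc(doc_id, [b])
    gold = _smurf_gold(doc_id, doc.sentences[0], 2, 4, (0, 1), [(6, 7), (8, 9)])
    return Fixture(doc_id, doc, gold, phenomena=("passive",))


def _vb_prep_nominalization() -> Fixture:
    doc_id = "vb-prep-nominalization"
    b = SentenceBuilder()
    b.t("The", "DT", 1, "det", lemma="the")
    b.t("ubiquitination", "NN", 10, "nsubj")
    b.t("and", "CC", 3, "cc")
    b.t("degradation", "NN", 1, "conj")
    b.t("of", "IN", 5, "case")
    b.t("RhoA", "NNP", 1, "nmod_of")
    b.t("by", "IN", 7, "case")
    b.t("Smurf1", "NNP", 1, "nmod_by")
    b.t("and", "CC", 9, "cc")
    b.t("Smurf2", "NNP", 7, "conj")
    b.t("increased", "VBD", -1, "root", lemma="increase")
    b.t(".", ".", 10, "punct")
    doc = _doc(doc_id, [b])
    gold = _smurf_gold(doc_id, doc.sentences[0], 1, 3, (5, 6), [(7, 8), (9, 10)])
    return Fixture(doc_id, doc, gold, phenomena=("prepositional_nominalization",))


def _vb_obj_nominalization() -> Fixture:
    doc_id = "vb-obj-nominalization"
    b = SentenceBuilder()
    b.t("RhoA", "NNP", 1, "compound")
    b.t("ubiquitination", "NN", 8, "nsubj")
    b.t("and", "CC", 3, "cc")
    b.t("degradation", "NN", 1, "conj")
    b.t("by", "IN", 5, "case")
    b.t("Smurf1", "NNP", 1, "nmod_by")
    b.t("and", "CC", 7, "cc")
    b.t("Smurf2", "NNP", 5, "conj")
    b.t("increased", "VBD", -1, "root", lemma="increase")
    b.t(".", ".", 8, "punct")
    doc = _doc(doc_id, [b])
    gold = _smurf_gold(doc_id, doc.sentences[0], 1, 3, (0, 1), [(5, 6), (7, 8)])
    return Fixture(doc_id, doc, gold, phenomena=("object_nominalization",))


def _vb_subj_nominalization() -> Fixture:
    doc_id = "vb-subj-nominalization"
    b = SentenceBuilder()
    b.t("Smurf1", "NNP", 1, "compound")
    b.t("ubiquitination", "NN", 6, "nsubj")
    b.t("and", "CC", 3, "cc")
    b.t("degradation", "NN", 1, "conj")
    b.t("of", "IN", 5, "case")
    b.t("RhoA", "NNP", 1, "nmod_of")
    b.t("increased", "VBD", -1, "root", lemma="increase")
    b.t(".", ".", 6, "punct")
    doc = _doc(doc_id, [b])
    gold = _smurf_gold(doc_id, doc.sentences[0], 1, 3, (5, 6), [(0, 1)])
    return Fixture(doc_id, doc, gold, phenomena=("subject_nominalization",))


def _vb_subj_relclause() -> Fixture:
    doc_id = "vb-subj-relclause"
    b = SentenceBuilder()
    b.t("Its", "PRP$", 3, "det", lemma="its")
    b.t("many", "JJ", 3, "amod")
    b.t("abnormal", "JJ", 3, "amod")
    b.t("phenotypes", "NNS", 6, "nsubjpass")
    b.t("can", "MD", 6, "aux")
    b.t("be", "VB", 6, "auxpass", lemma="be")
    b.t("rescued", "VBN", -1, "root", lemma="rescue")
    b.t("via", "IN", 8, "case")
    b.t("Pde2", "NNP", 6, "nmod_via")
    b.t(",", ",", 8, "punct")
    b.t("which", "WDT", 12, "nsubj", lemma="which")
    b.t("specifically", "RB", 12, "advmod")
    b.t("hydrolyzes", "VBZ", 8, "acl:relcl", lemma="hydrolyze")
    b.t("cAMP", "NN", 12, "obj", lemma="cAMP")
    b.t(".", ".", 6, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 8, 9)
    t = _mention(doc_id, 0, sent, 13, 14, etype="simple_chemical")
    ev = _simple(doc_id, 0, sent, "hydrolysis", 12, t)
    gold = GoldAnnotation(
        doc_id, mentions=[c, t],
        events=[ev, _reg(doc_id, 0, sent, +1, 12, c, ev)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("subject_relative_clause",))


def _vb_obj_relclause() -> Fixture:
    doc_id = "vb-obj-relclause"
    b = SentenceBuilder()
    b.t("We", "PRP", 1, "nsubj", lemma="we")
    b.t("measured", "VBD", -1, "root", lemma="measure")
    b.t("transcription", "NN", 3, "compound")
    b.t("activation", "NN", 1, "obj")
    b.t("in", "IN", 6, "case")
    b.t("the", "DT", 6, "det")
    b.t("presence", "NN", 1, "nmod_in")
    b.t("of", "IN", 8, "case")
    b.t("cAMP", "NN", 6, "nmod_of", lemma="cAMP")
    b.t(",", ",", 8, "punct")
    b.t("which", "WDT", 12, "nsubjpass", lemma="which")
    b.t("is", "VBZ", 12, "auxpass", lemma="be")
    b.t("hydrolyzed", "VBN", 8, "acl:relcl", lemma="hydrolyze")
    b.t("by", "IN", 14, "case")
    b.t("CRP", "NNP", 12, "nmod_by")
    b.t(".", ".", 1, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    t = _mention(doc_id, 0, sent, 8, 9, etype="simple_chemical")
    c = _mention(doc_id, 0, sent, 14, 15)
    ev = _simple(doc_id, 0, sent, "hydrolysis", 12, t)
    gold = GoldAnnotation(
        doc_id, mentions=[t, c],
        events=[ev, _reg(doc_id, 0, sent, +1, 12, c, ev)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("object_relative_clause",))


def _vb_subj_apposition() -> Fixture:
    doc_id = "vb-subj-apposition"
    b = SentenceBuilder()
    b.t("Via", "IN", 5, "case", lemma="via")
    b.t("yeast", "NN", 5, "compound")
    b.t("two", "CD", 4, "compound", lemma="two")
    b.t("-", "HYPH", 2, "punct", glue=True)
    b.t("hybrid", "NN", 5, "compound", glue=True)
    b.t("screening", "NN", 8, "nmod_via")
    b.t(",", ",", 8, "punct")
    b.t("we", "PRP", 8, "nsubj", lemma="we")
    b.t("found", "VBD", -1, "root", lemma="find")
    b.t("that", "IN", 16, "mark", lemma="that")
    b.t("a", "DT", 12, "det")
    b.t("novel", "JJ", 12, "amod")
    b.t("protein", "NN", 16, "nsubj")
    b.t(",", ",", 12, "punct")
    b.t("A20", "NNP", 12, "appos")
    b.t(",", ",", 12, "punct")
    b.t("binds", "VBZ", 8, "ccomp", lemma="bind")
    b.t("to", "IN", 18, "case")
    b.t("ABIN", "NNP", 16, "nmod_to")
    b.t(".", ".", 8, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    a = _mention(doc_id, 0, sent, 14, 15)
    c = _mention(doc_id, 0, sent, 18, 19)
    gold = GoldAnnotation(
        doc_id, mentions=[a, c],
        events=[_binding(doc_id, 0, sent, 16, a, c)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("subject_apposition",))


def _vb_obj_apposition() -> Fixture:
    doc_id = "vb-obj-apposition"
    b = SentenceBuilder()
    b.t("Via", "IN", 5, "case", lemma="via")
    b.t("yeast", "NN", 5, "compound")
    b.t("two", "CD", 4, "compound", lemma="two")
    b.t("-", "HYPH", 2, "punct", glue=True)
    b.t("hybrid", "NN", 5, "compound", glue=True)
    b.t("screening", "NN", 8, "nmod_via")
    b.t(",", ",", 8, "punct")
    b.t("we", "PRP", 8, "nsubj", lemma="we")
    b.t("found", "VBD", -1, "root", lemma="find")
    b.t("that", "IN", 11, "mark", lemma="that")
    b.t("A20", "NNP", 11, "nsubj")
    b.t("binds", "VBZ", 8, "ccomp", lemma="bind")
    b.t("to", "IN", 15, "case")
    b.t("a", "DT", 15, "det")
    b.t("novel", "JJ", 15, "amod")
    b.t("protein", "NN", 11, "nmod_to")
    b.t(",", ",", 15, "punct")
    b.t("ABIN", "NNP", 15, "appos")
    b.t(".", ".", 8, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    a = _mention(doc_id, 0, sent, 10, 11)
    c = _mention(doc_id, 0, sent, 17, 18)
    gold = GoldAnnotation(
        doc_id, mentions=[a, c],
        events=[_binding(doc_id, 0, sent, 11, a, c)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("object_apposition",))


def _vb_paraphrastic() -> Fixture:
    doc_id = "vb-paraphrastic"
    b = SentenceBuilder()
    b.t("Smurf1", "NNP", 1, "nsubj")
    b.t("causes", "VBZ", -1, "root", lemma="cause")
    b.t("the", "DT", 3, "det")
    b.t("degradation", "NN", 1, "obj")
    b.t("of", "IN", 5, "case")
    b.t("RhoA", "NNP", 3, "nmod_of")
    b.t(".", ".", 1, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 0, 1)
    t = _mention(doc_id, 0, sent, 5, 6)
    ev = _simple(doc_id, 0, sent, "hydrolysis", 3, t)
    gold = GoldAnnotation(
        doc_id, mentions=[c, t],
        events=[ev, _reg(doc_id, 0, sent, +1, 3, c, ev)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("paraphrastic_causative",))


def _vb_combination() -> Fixture:
    doc_id = "vb-combination"
    b = SentenceBuilder()
    b.t("Pde2", "NNP", 10, "nsubj")
    b.t(",", ",", 0, "punct")
    b.t("which", "WDT", 5, "nsubjpass", lemma="which")
    b.t("has", "VBZ", 5, "aux", lemma="have")
    b.t("been", "VBN", 5, "auxpass", lemma="be")
    b.t("found", "VBN", 0, "acl:relcl", lemma="find")
    b.t("to", "TO", 7, "mark")
    b.t("hydrolyze", "VB", 5, "xcomp", lemma="hydrolyze")
    b.t("Ras", "NNP", 7, "obj")
    b.t(",", ",", 0, "punct")
    b.t("activates", "VBZ", -1, "root", lemma="activate")
    b.t("MEK", "NNP", 10, "obj")
    b.t(".", ".", 10, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 0, 1)
    t = _mention(doc_id, 0, sent, 8, 9)
    m = _mention(doc_id, 0, sent, 11, 12)
    ev = _simple(doc_id, 0, sent, "hydrolysis", 7, t)
    gold = GoldAnnotation(
        doc_id, mentions=[c, t, m],
        events=[ev, _reg(doc_id, 0, sent, +1, 7, c, ev),
                _reg(doc_id, 0, sent, +1, 10, c, m)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("combination",))


def _vb_polarity() -> Fixture:
    doc_id = "vb-polarity"
    b = SentenceBuilder()
    b.t("decreased", "JJ", 2, "amod", lemma="decreased")
    b.t("PTPN13", "NNP", 2, "compound")
    b.t("expression", "NN", 3, "nsubj")
    b.t("enhances", "VBZ", -1, "root", lemma="enhance")
    b.t("EphrinB1", "NNP", 5, "compound")
    b.t("phosphorylation", "NN", 3, "obj")
    b.t(".", ".", 3, "punct")
    doc = _doc(doc_id, [b])
    sent = doc.sentences[0]
    c = _mention(doc_id, 0, sent, 1, 2)
    t = _mention(doc_id, 0, sent, 4, 5)
    ev = _simple(doc_id, 0, sent, "phosphorylation", 5, t)
    gold = GoldAnnotation(
        doc_id, mentions=[c, t],
        events=[ev, _reg(doc_id, 0, sent, -1, 3, c, ev)],
    )
    return Fixture(doc_id, doc, gold, phenomena=("polarity",))


def _vb_coref_hp1g() -> Fixture:
    doc_id = "vb-coref-hp1g"
    b1 = SentenceBuilder()
    b1.t("We", "PRP", 1, "nsubj", lemma="we")
    b1.t("studied", "VBD", -1, "root", lemma="study")
    b1.t("the", "DT", 3, "det")
    b1.t("function", "NN", 1, "obj")
    b1.t("of", "IN", 5, "case")
    b1.t("HP1γ", "NNP", 3, "nmod_of", lemma="HP1γ")
    b1.t("in", "IN", 7, "case")
    b1.t("gametes", "NNS", 1, "nmod_in")
    b1.t(".", ".", 1, "punct")
    b2 = SentenceBuilder()
    b2.t("We", "PRP", 1, "nsubj", lemma="we")
    b2.t("demonstrate", "VBP", -1, "root", lemma="demonstrate")
    b2.t("that", "IN", 9, "mark", lemma="that")
    b2.t("phosphorylation", "NN", 9, "nsubj")
    b2.t("of", "IN", 6, "case")
    b2.t("this", "DT", 6, "det", lemma="this")
    b2.t("protein", "NN", 3, "nmod_of")
    b2.t("at", "IN", 8, "case")
    b2.t("S83", "NNP", 3, "nmod_at")
    b2.t("occurs", "VBZ", 1, "ccomp", lemma="occur")
    b2.t("in", "IN", 11, "case")
    b2.t("response", "NN", 9, "nmod_in")
    b2.t("to", "IN", 14, "case")
    b2.t("Aurora", "NNP", 14, "compound")
    b2.t("A", "NNP", 11, "nmod_to")
    b2.t(".", ".", 1, "punct")
    doc = _doc(doc_id, [b1, b2])
    s1, s2 = doc.sentences
    m = _mention(doc_id, 0, s1, 5, 6)
    alias = _mention(doc_id, 1, s2, 6, 7)
    alias.text = "HP1γ"
    site = _mention(doc_id, 1, s2, 8, 9, etype="site")
    ev = _simple(doc_id, 1, s2, "phosphorylation", 3, alias, site=site)
    ev.coref = True
    gold = GoldAnnotation(
        doc_id, mentions=[m, site], events=[ev],
        links=[((1, 6, 7), (0, 5, 6))],
    )
    return Fixture(doc_id, doc, gold, phenomena=("coref", "coref_entity"))


def _vb_coref_k134a() -> Fixture:
    doc_id = "vb-coref-k134a"
    b1 = SentenceBuilder()
    b1.t("We", "PRP", 1, "nsubj", lemma="we")
    b1.t("prepared", "VBD", -1, "root", lemma="prepare")
    b1.t("recombinant", "JJ", 3, "amod")
    b1.t("H2AX", "NNP", 1, "obj")
    b1.t("-", "HYPH", 3, "punct", glue=True)
    b1.t("K134A", "NNP", 3, "dep", glue=True)
    b1.t(".", ".", 1, "punct")
    b2 = SentenceBuilder()
    b2.t("Methylation", "NN", 7, "nsubjpass", lemma="methylation")
    b2.t("of", "IN", 4, "case")
    b2.t("the", "DT", 4, "det")
    b2.t("K134A", "NNP", 4, "compound")
    b2.t("mutant", "NN", 0, "nmod_of")
    b2.t("was", "VBD", 7, "auxpass", lemma="be")
    b2.t("strongly", "RB", 7, "advmod")
    b2.t("diminished", "VBN", -1, "root", lemma="diminish")
    b2.t(".", ".", 7, "punct")
    doc = _doc(doc_id, [b1, b2])
    s1, s2 = doc.sentences
    m = _mention(doc_id, 0, s1, 3, 4)
    m.modifications.append(Modification("Mutant", variant="K134A", evidence=(4, 6)))
    alias = _mention(doc_id, 1, s2, 3, 5)
    alias.text = "H2AX"
    ev = _simple(doc_id, 1, s2, "methylation", 0, alias)
    ev.coref = True
    gold = GoldAnnotation(
        doc_id, mentions=[m], events=[ev],
        links=[((1, 3, 5), (0, 3, 4))],
    )
    return Fixture(doc_id, doc, gold, phenomena=("coref", "coref_mutant"))


def _vb_coref_ll37() -> Fixture:
    doc_id = "vb-coref-ll37"
    b1 = SentenceBuilder()
    b1.t("LL", "NNP", 2, "compound")
    b1.t("-", "HYPH", 2, "punct", glue=True)
    b1.t("37", "CD", 3, "nsubj", glue=True)
    b1.t("forms", "VBZ", -1, "root", lemma="form")
    b1.t("a", "DT", 5, "det")
    b1.t("complex", "NN", 3, "obj")
    b1.t("together", "RB", 3, "advmod")
    b1.t("with", "IN", 11, "case")
    b1.t("the", "DT", 11, "det")
    b1.t("IGF", "NNP", 11, "compound")
    b1.t("-", "HYPH", 11, "punct", glue=True)
    b1.t("1R", "NNP", 5, "nmod_with", glue=True)
    b1.t(".", ".", 3, "punct")
    b2 = SentenceBuilder()
    b2.t("In", "IN", 1, "case")
    b2.t("contrast", "NN", 7, "nmod_in")
    b2.t(",", ",", 7, "punct")
    b2.t("aPKC", "NNP", 4, "compound")
    b2.t("inhibitors", "NNS", 7, "nsubj")
    b2.t("did", "VBD", 7, "aux", lemma="do")
    b2.t("not", "RB", 7, "neg", lemma="not")
    b2.t("block", "VB", -1, "root", lemma="block")
    b2.t("this", "DT", 9, "det", lemma="this")
    b2.t("interaction", "NN", 7, "obj")
    b2.t(".", ".", 7, "punct")
    doc = _doc(doc_id, [b1, b2])
    s1, s2 = doc.sentences
    ll = _mention(doc_id, 0, s1, 0, 3)
    igf = _mention(doc_id, 0, s1, 9, 12)
    apkc = _mention(doc_id, 1, s2, 3, 4)
    bind = _binding(doc_id, 0, s1, 5, ll, igf)
    bind_alias = EventMention(
        doc_id=doc_id, sent_index=1, label="binding", trigger=(9, 10),
        trigger_text="interaction",
        arguments={"theme": [ll, igf]}, coref=True,
    )
    neg = _reg(doc_id, 1, s2, -1, 7, apkc, bind_alias, negated=True)
    neg.coref = True
    gold = GoldAnnotation(
        doc_id, mentions=[ll, igf, apkc], events=[bind, neg],
        links=[((1, 9, 10), (0, 5, 6))],
    )
    return Fixture(doc_id, doc, gold, phenomena=("coref", "coref_event", "negation"))


def verbatim_fixtures() -> list[Fixture]:
    """Hand-annotated fixtures for the published example sentences."""
    return [
        _vb_declarative(),
        _vb_passive(),
        _vb_prep_nominalization(),
        _vb_obj_nominalization(),
        _vb_subj_nominalization(),
        _vb_subj_relclause(),
        _vb_obj_relclause(),
        _vb_subj_apposition(),
        _vb_obj_apposition(),
        _vb_paraphrastic(),
        _vb_combination(),
        _vb_polarity(),
        _vb_coref_hp1g(),
        _vb_coref_k134a(),
        _vb_coref_ll37(),
    ]
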