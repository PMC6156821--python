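"""Sentence/token segmentation and dependency-annotated documents.

Tokenization follows biomedical conventions: dashes and slashes flanked
by alphanumeric characters are word separators (so ``GAP-mediated``
becomes three tokens and complex members like ``Dvl2/aPKC`` are
exposed).  Documents carry 0-based, half-open, document-level character
offsets throughout, and dependency annotation is stored as basic
(single-head) trees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence, TextIO

#: sentinel head index for the root of a dependency tree
ROOT = -1

#: Stanford-style dependency labels mapped onto the canonical set used
#: by the shipped grammars (Universal-Dependencies-flavoured, with
#: collapsed prepositions spelled ``nmod_<prep>``).
LABEL_ALIASES: dict[str, str] = {
    "dobj": "obj",
    "nsubj:pass": "nsubjpass",
    "aux:pass": "auxpass",
    "nn": "compound",
    "rcmod": "acl:relcl",
    "acl_relcl": "acl:relcl",
    "vmod": "acl",
    "num": "nummod",
}
_PREP_RE = re.compile(r"^(?:prep|nmod|obl)[_:]([a-z_]+)$")


def canonical_label(label: str) -> str:
    """Normalize a dependency label to the canonical set.

    ``prep_of``/``nmod:of``/``obl:of`` all become ``nmod_of``; Stanford
    labels are mapped through :data:`LABEL_ALIASES`; anything else is
    passed through unchanged.
    """
    m = _PREP_RE.match(label)
    if m:
        return f"nmod_{m.group(1)}"
    return LABEL_ALIASES.get(label, label)


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    start: int
    end: int
    pos: str = "_"
    lemma: str = "_"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty token span [{self.start},{self.end})")


@dataclass(frozen=True)
class DependencyEdge:
    head: int  # token index, or ROOT
    dependent: int
    label: str


@dataclass
class Sentence:
    tokens: list[Token]
    deps: list[DependencyEdge] = field(default_factory=list)
    text: str = ""

    # -- graph helpers -------------------------------------------------
    def head_of(self, index: int) -> tuple[int, str] | None:
        for e in self.deps:
            if e.dependent == index:
                return e.head, e.label
        return None

    def children(self, index: int) -> list[tuple[int, str]]:
        return [(e.dependent, e.label) for e in self.deps if e.head == index]

    def root(self) -> int:
        for e in self.deps:
            if e.head == ROOT:
                return e.dependent
        raise StructureError("sentence has no ROOT edge")

    @property
    def start(self) -> int:
        return self.tokens[0].start

    @property
    def end(self) -> int:
        return self.tokens[-1].end

    def span_text(self, start: int, end: int) -> str:
        """Raw text covered by tokens [start, end) including gaps."""
        return self.text[
            self.tokens[start].start - self.start : self.tokens[end - 1].end - self.start
        ]


@dataclass
class Document:
    doc_id: str
    sentences: list[Sentence]
    raw_text: str = ""


class ConlluParseError(ValueError):
    pass


class StructureError(ValueError):
    pass


class AnnotationError(RuntimeError):
    pass


# ---------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------

#: lower-cased words that commonly precede a non-terminal period
ABBREVIATIONS = frozenset(
    {
        "fig", "figs", "et", "al", "e.g", "i.e", "cf", "ca", "vs", "dr",
        "approx", "no", "ref", "refs", "eq", "etc", "resp", "inc", "st",
    }
)

_TERMINAL_RE = re.compile(r"[.!?]+")


def segment_sentences(
    raw_text: str, abbreviations: frozenset[str] | None = None
) -> list[tuple[int, int]]:
    """Split ``raw_text`` into sentence character spans.

    Returns 0-based half-open spans that are disjoint, ordered and cover
    every non-whitespace character.  A terminal-punctuation run ends a
    sentence unless the preceding word is a known abbreviation or the
    next non-space character is lower-case.
    """
    abbreviations = ABBREVIATIONS if abbreviations is None else abbreviations
    spans: list[tuple[int, int]] = []
    cursor = 0
    n = len(raw_text)
    for m in _TERMINAL_RE.finditer(raw_text):
        end = m.end()
        if end < n and not raw_text[end].isspace():
            continue  # e.g. "3.5-fold" — no boundary inside a token
        before = raw_text[cursor : m.start()]
        word = re.search(r"([\w.]+)\s*$", before)
        if word and word.group(1).rstrip(".").lower() in abbreviations:
            continue
        nxt = re.search(r"\S", raw_text[end:])
        if nxt and raw_text[end + nxt.start()].islower():
            continue
        spans.append((cursor, end))
        cursor = end
    if re.search(r"\S", raw_text[cursor:]):
        spans.append((cursor, n))
    # trim whitespace at both ends of each span
    trimmed = []
    for s, e in spans:
        chunk = raw_text[s:e]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if s + lead < e - trail:
            trimmed.append((s + lead, e - trail))
    return trimmed


# ---------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------

# word pieces: decimal numbers stay whole, alphanumeric runs stay whole,
# every other non-space character (dash, slash, parens, ...) is its own
# token — which realizes the dash/slash splitting rule, since a dash
# inside an alphanumeric chunk falls out as a separate token.
_PIECE_RE = re.compile(r"\d+(?:[.,]\d+)+|\w+|[^\w\s]", re.UNICODE)


def tokenize(sentence_text: str, sentence_offset: int = 0) -> list[Token]:
    """Tokenize one sentence; offsets are document-level."""
    tokens: list[Token] = []
    for m in _PIECE_RE.finditer(sentence_text):
        tokens.append(
            Token(
                index=len(tokens),
                text=m.group(),
                start=sentence_offset + m.start(),
                end=sentence_offset + m.end(),
            )
        )
    return tokens


def segment_document(raw_text: str, doc_id: str = "doc") -> Document:
    """Segment + tokenize plain text into an unannotated Document."""
    sentences = []
    for s, e in segment_sentences(raw_text):
        sentences.append(Sentence(tokens=tokenize(raw_text[s:e], s), text=raw_text[s:e]))
    return Document(doc_id=doc_id, sentences=sentences, raw_text=raw_text)


# ---------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------


def validate_sentence(sentence: Sentence) -> None:
    """Check the Sentence invariants; raise StructureError on violation."""
    n = len(sentence.tokens)
    heads: dict[int, int] = {}
    roots = 0
    for e in sentence.deps:
        if not 0 <= e.dependent < n:
            raise StructureError(f"dependent index {e.dependent} out of range")
        if e.head == ROOT:
            roots += 1
        elif not 0 <= e.head < n:
            raise StructureError(f"head index {e.head} out of range")
        if e.dependent in heads:
            raise StructureError(f"token {e.dependent} has two heads")
        heads[e.dependent] = e.head
    if sentence.deps:
        if roots != 1:
            raise StructureError(f"expected exactly one ROOT edge, got {roots}")
        if len(heads) != n:
            missing = sorted(set(range(n)) - set(heads))
            raise StructureError(f"tokens without a head: {missing}")
        # acyclicity: walk up from every node
        for start in range(n):
            seen = set()
            node = start
            while node != ROOT:
                if node in seen:
                    raise StructureError(f"cycle through token {node}")
                seen.add(node)
                node = heads[node]


# ---------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------

_MISC_OFF_RE = re.compile(r"start=(\d+)\|end=(\d+)")


def _parse_misc_offsets(misc: str) -> tuple[int, int] | None:
    m = _MISC_OFF_RE.search(misc)
    if m:
        return int(m.group(1)), int(m.group(2))
    return None


def read_conllu_corpus(stream: TextIO | Iterable[str]) -> list[Document]:
    """Read one or more documents (split on ``# newdoc id``) from CoNLL-U."""
    docs: list[Document] = []
    cur_id = "doc"
    cur_sents: list[Sentence] = []
    block: list[tuple[int, str]] = []
    comments: list[str] = []

    def flush_doc() -> None:
        nonlocal cur_sents
        if cur_sents:
            docs.append(_assemble_document(cur_id, cur_sents))
            cur_sents = []

    def flush_block() -> None:
        nonlocal block, comments
        if block:
            cur_sents.append(_parse_sentence_block(block, comments))
        block, comments = [], []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush_block()
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*newdoc(?:\s+id\s*=\s*(.*))?", line)
            if m:
                flush_block()
                flush_doc()
                cur_id = (m.group(1) or "doc").strip()
            else:
                comments.append(line)
            continue
        block.append((lineno, line))
    flush_block()
    flush_doc()
    return docs


def read_conllu(stream: TextIO | Iterable[str]) -> Document:
    """Read a single document from CoNLL-U (first ``newdoc`` if several)."""
    docs = read_conllu_corpus(stream)
    if not docs:
        return Document(doc_id="doc", sentences=[], raw_text="")
    return docs[0]


def _parse_sentence_block(
    block: list[tuple[int, str]], comments: list[str]
) -> Sentence:
    rows = []
    for lineno, line in block:
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConlluParseError(
                f"line {lineno}: expected 10 tab-separated columns, got {len(cols)}"
            )
        tid, form, lemma, upos, xpos, _feats, head, deprel, _deps, misc = cols
        if "-" in tid or "." in tid:
            continue  # multiword/empty nodes are not produced by this package
        try:
            idx = int(tid)
            head_i = int(head)
        except ValueError as exc:
            raise ConlluParseError(f"line {lineno}: non-integer ID/HEAD") from exc
        rows.append((lineno, idx, form, lemma, upos, xpos, head_i, deprel, misc))

    text = None
    for c in comments:
        m = re.match(r"#\s*text\s*=\s*(.*)", c)
        if m:
            text = m.group(1)

    n = len(rows)
    tokens: list[Token] = []
    deps: list[DependencyEdge] = []
    offsets_known = all(_parse_misc_offsets(r[8]) for r in rows) and n > 0
    cursor = 0
    for lineno, idx, form, lemma, upos, xpos, head_i, deprel, misc in rows:
        if idx != len(tokens) + 1:
            raise ConlluParseError(f"line {lineno}: non-consecutive token ID {idx}")
        if offsets_known:
            start, end = _parse_misc_offsets(misc)  # type: ignore[misc]
        else:
            start, end = cursor, cursor + len(form)
            cursor = end + 1
        pos = xpos if xpos != "_" else upos
        tokens.append(Token(len(tokens), form, start, end, pos=pos, lemma=lemma))
        if not 0 <= head_i <= n:
            raise StructureError(
                f"line {lineno}: HEAD {head_i} points outside sentence of {n} tokens"
            )
        deps.append(
            DependencyEdge(
                head=ROOT if head_i == 0 else head_i - 1,
                dependent=len(tokens) - 1,
                label=canonical_label(deprel),
            )
        )
    if text is None:
        text = _reconstruct_text(tokens)
    sent = Sentence(tokens=tokens, deps=deps, text=text)
    validate_sentence(sent)
    return sent


def _reconstruct_text(tokens: Sequence[Token]) -> str:
    if not tokens:
        return ""
    base = tokens[0].start
    out = []
    prev_end = base
    for t in tokens:
        out.append(" " * (t.start - prev_end))
        out.append(t.text)
        prev_end = t.end
    return "".join(out)


def _assemble_document(doc_id: str, sentences: list[Sentence]) -> Document:
    # If per-token offsets were absent the sentences start at 0 each;
    # rebase them so document spans are disjoint and ordered.
    rebased: list[Sentence] = []
    cursor = 0
    pieces: list[str] = []
    for sent in sentences:
        if rebased and sent.tokens and sent.tokens[0].start <= rebased[-1].tokens[-1].end:
            shift = cursor - sent.tokens[0].start
            sent = Sentence(
                tokens=[replace(t, start=t.start + shift, end=t.end + shift) for t in sent.tokens],
                deps=sent.deps,
                text=sent.text,
            )
        rebased.append(sent)
        pieces.append(sent.text)
        cursor = sent.tokens[-1].end + 1 if sent.tokens else cursor
    raw = " ".join(pieces)
    return Document(doc_id=doc_id, sentences=rebased, raw_text=raw)


def write_conllu(document: Document, stream: TextIO) -> None:
    """Serialize a Document to CoNLL-U with offsets in MISC."""
    stream.write(f"# newdoc id = {document.doc_id}\n")
    for i, sent in enumerate(document.sentences):
        stream.write(f"# sent_id = {document.doc_id}.{i}\n")
        stream.write(f"# text = {sent.text}\n")
        head_by_dep = {e.dependent: (e.head, e.label) for e in sent.deps}
        for t in sent.tokens:
            head, label = head_by_dep.get(t.index, (ROOT, "dep"))
            stream.write(
                "\t".join(
                    [
                        str(t.index + 1),
                        t.text,
                        t.lemma,
                        "_",
                        t.pos,
                        "_",
                        str(0 if head == ROOT else head + 1),
                        label,
                        "_",
                        f"start={t.start}|end={t.end}",
                    ]
                )
                + "\n"
            )
        stream.write("\n")


# ---------------------------------------------------------------------
# pluggable annotation
# ---------------------------------------------------------------------

#: A parser provider maps a token-text list to per-token
#: (pos, lemma, head, label) tuples; ``head`` is a 0-based index or ROOT.
ParserProvider = Callable[[list[str]], list[tuple[str, str, int, str]]]

_PROVIDERS: dict[str, ParserProvider] = {}


def register_provider(name: str, provider: ParserProvider) -> None:
    _PROVIDERS[name] = provider


def get_provider(name: str) -> ParserProvider:
    try:
        return _PROVIDERS[name]
    except KeyError:
        raise KeyError(f"no parser provider registered under {name!r}") from None


def annotate(document: Document, provider: ParserProvider) -> Document:
    """Fill POS/lemma/deps on sentences that lack them.

    Already-annotated sentences pass through untouched, so documents
    read from CoNLL-U bypass the provider entirely.
    """
    out_sents = []
    for si, sent in enumerate(document.sentences):
        if sent.deps:
            out_sents.append(sent)
            continue
        try:
            rows = provider([t.text for t in sent.tokens])
        except Exception as exc:
            raise AnnotationError(
                f"parser provider failed on doc {document.doc_id!r}, sentence {si}: {exc}"
            ) from exc
        tokens = [
            replace(t, pos=pos, lemma=lemma)
            for t, (pos, lemma, _h, _l) in zip(sent.tokens, rows)
        ]
        deps = [
            DependencyEdge(head=h, dependent=i, label=canonical_label(lbl))
            for i, (_p, _lm, h, lbl) in enumerate(rows)
        ]
        new = Sentence(tokens=tokens, deps=deps, text=sent.text)
        validate_sentence(new)
        out_sents.append(new)
    return Document(document.doc_id, out_sents, document.raw_text)


def iter_sentences(docs: Iterable[Document]) -> Iterator[tuple[Document, int, Sentence]]:
    for doc in docs:
        for i, sent in enumerate(doc.sentences):
            yield doc, i, sent
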