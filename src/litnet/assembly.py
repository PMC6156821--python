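"""Assembly of event mentions into an evidence-counted interaction network.

Events are normalized to directed records over grounding ids, evidence
is aggregated at paper granularity (distinct document ids), a
redundancy filter keeps records attested in at least ``k`` papers, and
the result can be merged with a curated prior network in SIF form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from litnet.entities import EntityMention
from litnet.events import EventMention

log = logging.getLogger(__name__)

RELATIONS = ("controls_state_change", "in_complex_with", "controls_activity")


class SifParseError(ValueError):
    pass


@dataclass
class InteractionRecord:
    source: str  # grounding id "ns:ident"
    relation: str
    subtype: str | None  # state-change event label
    sign: int
    target: str
    evidence_count: int = 0
    provenance: list[tuple[str, int, str]] = field(default_factory=list)
    negated_evidence_count: int = 0
    autoregulation: bool = False

    def edge_key(self) -> tuple:
        return (self.source, self.relation, self.subtype, self.sign, self.target)

    def sif_relation(self) -> str:
        sign = "pos" if self.sign > 0 else "neg"
        if self.relation == "in_complex_with":
            return "in-complex-with"
        if self.relation == "controls_activity":
            return f"controls-activity-{sign}"
        return f"controls-{self.subtype}-{sign}"


@dataclass(frozen=True)
class PriorEdge:
    source: str
    relation: str
    target: str
    origin: str = "curated"  # "curated" | "extracted"


@dataclass
class PriorNetwork:
    edges: list[PriorEdge] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(e.source, e.relation, e.target) for e in self.edges}


# ---------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------


def _participant_grounding(arg) -> str | None:
    if isinstance(arg, EntityMention):
        return arg.grounding_id()
    if isinstance(arg, EventMention):
        # event-typed participant (chained control): fall back to its
        # first grounded entity participant
        for sub in arg.participants():
            g = _participant_grounding(sub)
            if g is not None:
                return g
    return None


def _first(event: EventMention, role: str):
    vals = event.arguments.get(role, [])
    return vals[0] if vals else None


def normalize(events: Sequence[EventMention]) -> list[InteractionRecord]:
    """Summarize events into directed records over grounding ids.

    Regulations of a simple event become ``controls_state_change``
    edges typed by the inner event label; activations become
    ``controls_activity``; binding becomes symmetric
    ``in_complex_with`` (canonically ordered).  Ungrounded participants
    drop the record (logged).  Negated events yield records flagged
    through a single-item negated provenance so that aggregation can
    count them without asserting the edge.
    """
    records: list[InteractionRecord] = []
    for ev in events:
        rec = _normalize_one(ev)
        if rec is not None:
            records.append(rec)
    return records


def _normalize_one(ev: EventMention) -> InteractionRecord | None:
    if ev.label in ("positive_regulation", "negative_regulation"):
        controller = _first(ev, "controller")
        controlled = _first(ev, "controlled")
        if not isinstance(controlled, EventMention):
            return None
        src = _participant_grounding(controller)
        theme = _first(controlled, "theme")
        tgt = _participant_grounding(theme)
        if src is None or tgt is None:
            log.info("dropping ungrounded regulation at %s/%s", ev.doc_id, ev.sent_index)
            return None
        return _record(ev, src, "controls_state_change", controlled.label, ev.sign, tgt)
    if ev.label in ("positive_activation", "negative_activation"):
        controller = _first(ev, "controller")
        controlled = _first(ev, "controlled")
        src = _participant_grounding(controller)
        tgt = _participant_grounding(controlled)
        if src is None or tgt is None:
            log.info("dropping ungrounded activation at %s/%s", ev.doc_id, ev.sent_index)
            return None
        return _record(ev, src, "controls_activity", None, ev.sign, tgt)
    if ev.label == "binding":
        themes = ev.arguments.get("theme", [])
        ids = [g for g in (_participant_grounding(t) for t in themes) if g is not None]
        if len(ids) < 2:
            log.info("dropping ungrounded binding at %s/%s", ev.doc_id, ev.sent_index)
            return None
        a, b = sorted(ids[:2])
        return _record(ev, a, "in_complex_with", None, +1, b)
    return None  # bare simple events carry no directed edge


def _record(
    ev: EventMention, src: str, relation: str, subtype: str | None, sign: int, tgt: str
) -> InteractionRecord:
    rec = InteractionRecord(
        source=src,
        relation=relation,
        subtype=subtype,
        sign=sign,
        target=tgt,
        autoregulation=(src == tgt),
    )
    prov = (ev.doc_id, ev.sent_index, ev.trigger_text)
    if ev.negated:
        rec.negated_evidence_count = 1
        rec.provenance = []
        rec.evidence_count = 0
        rec.negated_provenance = [prov]  # type: ignore[attr-defined]
    else:
        rec.provenance = [prov]
        rec.evidence_count = 1
    return rec


# ---------------------------------------------------------------------
# aggregation and filtering
# ---------------------------------------------------------------------


def aggregate(
    records: Iterable[InteractionRecord], granularity: str = "paper"
) -> list[InteractionRecord]:
    """Merge identical edges; evidence counts distinct papers by default.

    ``granularity="mention"`` counts every supporting mention instead.
    Records supported only by negated statements are dropped; negated
    statements matching an asserted edge increment its
    ``negated_evidence_count``.
    """
    if granularity not in ("paper", "mention"):
        raise ValueError(f"unknown granularity {granularity!r}")
    merged: dict[tuple, InteractionRecord] = {}
    order: list[tuple] = []
    for rec in records:
        k = rec.edge_key()
        if k not in merged:
            merged[k] = InteractionRecord(
                source=rec.source, relation=rec.relation, subtype=rec.subtype,
                sign=rec.sign, target=rec.target, autoregulation=rec.autoregulation,
            )
            order.append(k)
        agg = merged[k]
        agg.provenance.extend(rec.provenance)
        agg.negated_evidence_count += rec.negated_evidence_count
    out = []
    for k in order:
        agg = merged[k]
        if not agg.provenance:
            continue  # only negated support
        if granularity == "paper":
            agg.evidence_count = len({doc for doc, _s, _t in agg.provenance})
        else:
            agg.evidence_count = len(agg.provenance)
        out.append(agg)
    return out


def filter_redundancy(
    records: Sequence[InteractionRecord], k: int = 2
) -> list[InteractionRecord]:
    """High-confidence subset: records seen in at least ``k`` papers."""
    if k < 1:
        raise ValueError("redundancy threshold must be >= 1")
    return [r for r in records if r.evidence_count >= k]


# ---------------------------------------------------------------------
# SIF + prior merge
# ---------------------------------------------------------------------


def read_sif(stream: TextIO | Iterable[str]) -> PriorNetwork:
    edges = []
    seen: set[PriorEdge] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) not in (3, 4):
            raise SifParseError(f"line {lineno}: expected 3-4 columns, got {len(cols)}")
        origin = cols[3] if len(cols) == 4 else "curated"
        edge = PriorEdge(cols[0], cols[1], cols[2], origin)
        if edge not in seen:
            seen.add(edge)
            edges.append(edge)
    return PriorNetwork(edges)


def write_sif(network: PriorNetwork, stream: TextIO, with_origin: bool = True) -> None:
    for e in network.edges:
        row = [e.source, e.relation, e.target]
        if with_origin:
            row.append(e.origin)
        stream.write("\t".join(row) + "\n")


def records_to_prior(records: Sequence[InteractionRecord]) -> PriorNetwork:
    edges = []
    seen = set()
    for r in records:
        e = PriorEdge(r.source, r.sif_relation(), r.target, "extracted")
        if e not in seen:
            seen.add(e)
            edges.append(e)
    return PriorNetwork(edges)


def merge_prior(
    records: Sequence[InteractionRecord], prior: PriorNetwork
) -> tuple[PriorNetwork, list[tuple[str, str, str]]]:
    """Union of extracted records with a curated prior, plus the overlap
    report (edges present in both).

    Edges are unique on (source, relation, target); an edge found on
    both sides keeps the origin tag ``both``.  The operation is
    commutative in edge content and idempotent.
    """
    extracted = records_to_prior(records)
    origins: dict[tuple[str, str, str], set[str]] = {}
    order: list[tuple[str, str, str]] = []
    for e in list(prior.edges) + list(extracted.edges):
        k = (e.source, e.relation, e.target)
        if k not in origins:
            origins[k] = set()
            order.append(k)
        if e.origin == "both":
            origins[k] |= {"curated", "extracted"}
        else:
            origins[k].add(e.origin)
    merged = []
    for k in order:
        tags = origins[k]
        tag = "both" if len(tags) > 1 else next(iter(tags))
        merged.append(PriorEdge(k[0], k[1], k[2], tag))
    overlap = sorted(prior.edge_set() & extracted.edge_set())
    return PriorNetwork(merged), overlap
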