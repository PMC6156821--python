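import io

import pytest
from hypothesis import given, strategies as st

from litnet.assembly import (
    InteractionRecord,
    PriorNetwork,
    SifParseError,
    aggregate,
    filter_redundancy,
    merge_prior,
    normalize,
    read_sif,
    records_to_prior,
    write_sif,
)
from litnet.entities import EntityMention
from litnet.events import EventMention


def _ent(name, gid, sent=0, start=0):
    return EntityMention(
        "doc", sent, start, start + 1, name, "gene_or_gene_product",
        groundings=[tuple(gid.split(":", 1))],
    )


def _simple(label, theme, doc="doc", sent=0, negated=False):
    return EventMention(
        doc_id=doc, sent_index=sent, label=label, trigger=(1, 2),
        trigger_text=label[:4], arguments={"theme": [theme]}, negated=negated,
    )


def _reg(sign, controller, controlled, doc="doc", sent=0, negated=False):
    return EventMention(
        doc_id=doc, sent_index=sent,
        label="positive_regulation" if sign > 0 else "negative_regulation",
        trigger=(1, 2), trigger_text="reg", sign=sign, negated=negated,
        arguments={"controller": [controller], "controlled": [controlled]},
    )


def _bind(a, b, doc="doc"):
    return EventMention(
        doc_id=doc, sent_index=0, label="binding", trigger=(1, 2),
        trigger_text="binds", arguments={"theme": [a, b]},
    )


SMURF = "uniprot:Q9HCE7"
RHOA = "uniprot:P61586"
A20 = "uniprot:P21580"
ABIN = "uniprot:Q15025"


# ---------------------------------------------------------------- normalize


def test_normalize_regulation_to_state_change():
    ev = _reg(+1, _ent("Smurf1", SMURF), _simple("ubiquitination", _ent("RhoA", RHOA, start=3)))
    [rec] = normalize([ev])
    assert (rec.source, rec.relation, rec.subtype, rec.sign, rec.target) == (
        SMURF, "controls_state_change", "ubiquitination", +1, RHOA,
    )


def test_normalize_binding_canonical_order():
    [rec] = normalize([_bind(_ent("ABIN", ABIN, start=3), _ent("A20", A20))])
    assert rec.relation == "in_complex_with"
    assert (rec.source, rec.target) == tuple(sorted([A20, ABIN]))


def test_normalize_activation():
    ev = EventMention(
        doc_id="doc", sent_index=0, label="negative_activation", trigger=(1, 2),
        trigger_text="inhibits", sign=-1,
        arguments={"controller": [_ent("A20", A20)],
                   "controlled": [_ent("RhoA", RHOA, start=3)]},
    )
    [rec] = normalize([ev])
    assert rec.relation == "controls_activity"
    assert rec.sign == -1


def test_normalize_empty():
    assert normalize([]) == []


def test_normalize_drops_ungrounded():
    ungrounded = EntityMention("doc", 0, 0, 1, "X", "gene_or_gene_product")
    ev = _reg(+1, ungrounded, _simple("ubiquitination", _ent("RhoA", RHOA, start=3)))
    assert normalize([ev]) == []


def test_normalize_bare_simple_event_no_edge():
    assert normalize([_simple("phosphorylation", _ent("RhoA", RHOA))]) == []


def test_normalize_conserves_provenance(extractions):
    from litnet.assembly import normalize as _normalize

    for _name, (fx, res) in extractions.items():
        for rec in _normalize(res.events):
            assert rec.evidence_count + rec.negated_evidence_count >= 1
            for doc, _sent, _trig in rec.provenance:
                assert doc == fx.document.doc_id


def test_normalize_event_controller_falls_back_to_participant():
    bind = _bind(_ent("A20", A20), _ent("ABIN", ABIN, start=3))
    ev = _reg(-1, bind, _simple("phosphorylation", _ent("RhoA", RHOA, start=5)))
    [rec, _bindrec] = normalize([ev, bind])
    assert rec.source == A20  # first grounded participant of the chain


# ---------------------------------------------------------------- aggregate


def _edge_records(doc_ids, negated=()):
    events = []
    for d in doc_ids:
        events.append(
            _reg(+1, _ent("Smurf1", SMURF), _simple("ubiquitination", _ent("RhoA", RHOA, start=3), doc=d), doc=d)
        )
    for d in negated:
        events.append(
            _reg(+1, _ent("Smurf1", SMURF),
                 _simple("ubiquitination", _ent("RhoA", RHOA, start=3), doc=d),
                 doc=d, negated=True)
        )
    return normalize(events)


def test_aggregate_two_docs():
    [rec] = aggregate(_edge_records(["d1", "d2"]))
    assert rec.evidence_count == 2


def test_aggregate_same_doc_counts_once():
    recs = _edge_records(["d1", "d1"])
    [agg] = aggregate(recs)
    # oracle: |distinct doc ids|
    assert agg.evidence_count == len({p[0] for r in recs for p in r.provenance}) == 1
    assert len(agg.provenance) == 2


def test_aggregate_mention_granularity():
    [agg] = aggregate(_edge_records(["d1", "d1"]), granularity="mention")
    assert agg.evidence_count == 2


def test_aggregate_opposite_signs_kept_separate():
    pos = _reg(+1, _ent("Smurf1", SMURF), _simple("ubiquitination", _ent("RhoA", RHOA, start=3)))
    neg = _reg(-1, _ent("Smurf1", SMURF), _simple("ubiquitination", _ent("RhoA", RHOA, start=3)))
    assert len(aggregate(normalize([pos, neg]))) == 2


def test_aggregate_negated_only_dropped():
    recs = _edge_records([], negated=["d1"])
    assert aggregate(recs) == []


def test_aggregate_negated_counts_on_asserted_edge():
    recs = _edge_records(["d1"], negated=["d2"])
    [agg] = aggregate(recs)
    assert agg.evidence_count == 1
    assert agg.negated_evidence_count == 1


def test_aggregate_unknown_granularity():
    with pytest.raises(ValueError):
        aggregate([], granularity="book")


# ---------------------------------------------------------------- filter


def _counted(counts):
    return [
        InteractionRecord("a", "controls_activity", None, 1, f"t{i}",
                          evidence_count=c, provenance=[("d", 0, "x")] * c)
        for i, c in enumerate(counts)
    ]


def test_filter_threshold():
    assert len(filter_redundancy(_counted([1, 2, 3]), k=2)) == 2


def test_filter_k1_identity():
    recs = _counted([1, 2, 3])
    assert filter_redundancy(recs, k=1) == recs


def test_filter_bad_k():
    with pytest.raises(ValueError):
        filter_redundancy([], k=0)


@given(st.lists(st.integers(min_value=1, max_value=6), max_size=25),
       st.integers(min_value=1, max_value=8))
def test_filter_matches_bruteforce_and_monotone(counts, k):
    recs = _counted(counts)
    got = filter_redundancy(recs, k=k)
    # oracle: list comprehension over counts
    assert got == [r for r in recs if r.evidence_count >= k]
    assert len(filter_redundancy(recs, k=k + 1)) <= len(got)


# ---------------------------------------------------------------- SIF merge


def test_read_sif_and_dedupe():
    net = read_sif(io.StringIO(
        "A\tin-complex-with\tB\nA\tin-complex-with\tB\nC\tcontrols-activity-pos\tD\n"
    ))
    assert len(net.edges) == 2


def test_read_sif_malformed_line():
    with pytest.raises(SifParseError, match="line 2"):
        read_sif(io.StringIO("A\tr\tB\nbroken line\n"))


def test_merge_union_and_overlap_oracle():
    extracted = aggregate(normalize([
        _reg(+1, _ent("Smurf1", SMURF), _simple("ubiquitination", _ent("RhoA", RHOA, start=3))),
        _bind(_ent("A20", A20), _ent("ABIN", ABIN, start=3)),
        _reg(-1, _ent("A20", A20), _simple("phosphorylation", _ent("RhoA", RHOA, start=3))),
    ]))
    assert len(extracted) == 3
    prior = read_sif(io.StringIO(
        f"{A20}\tin-complex-with\t{ABIN}\n"
        "uniprot:X\tcontrols-activity-pos\tuniprot:Y\n"
    ))
    merged, overlap = merge_prior(extracted, prior)
    ext_edges = records_to_prior(extracted).edge_set()
    # oracle: set union / intersection
    assert {(e.source, e.relation, e.target) for e in merged.edges} == (
        prior.edge_set() | ext_edges
    )
    assert len(merged.edges) == 4
    assert overlap == sorted(prior.edge_set() & ext_edges)
    assert len(overlap) == 1
    tag = {(e.source, e.relation, e.target): e.origin for e in merged.edges}
    assert tag[overlap[0]] == "both"


def test_merge_empty_prior():
    extracted = aggregate(normalize([_bind(_ent("A20", A20), _ent("ABIN", ABIN, start=3))]))
    merged, overlap = merge_prior(extracted, PriorNetwork())
    assert len(merged.edges) == 1 and overlap == []


def test_merge_idempotent_and_commutative():
    extracted = aggregate(normalize([_bind(_ent("A20", A20), _ent("ABIN", ABIN, start=3))]))
    prior = read_sif(io.StringIO(f"{A20}\tin-complex-with\t{ABIN}\n"))
    m1, _ = merge_prior(extracted, prior)
    m2, _ = merge_prior(extracted, m1)
    assert m1.edge_set() == m2.edge_set()


def test_write_sif_roundtrip():
    net = PriorNetwork(edges=read_sif(io.StringIO("A\tr\tB\tcurated\n")).edges)
    buf = io.StringIO()
    write_sif(net, buf)
    buf.seek(0)
    assert read_sif(buf).edges == net.edges
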