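"""JSON standoff serialization for mentions and (nested) events.

Events reference their arguments by id; nested event arguments point at
other event ids, so arbitrarily deep structures round-trip.  A light
schema check validates incoming documents (no external JSON-schema
dependency is required offline).
"""

from __future__ import annotations

import json
from typing import Sequence

from litnet.entities import EntityMention, Modification
from litnet.events import EventMention


class SchemaError(ValueError):
    pass


def _mod_to_dict(mod: Modification) -> dict:
    return {
        "kind": mod.kind,
        "subtype": mod.subtype,
        "variant": mod.variant,
        "site": mod.site,
        "evidence": list(mod.evidence) if mod.evidence else None,
    }


def _mention_to_dict(m: EntityMention) -> dict:
    return {
        "sent": m.sent_index,
        "span": [m.start, m.end],
        "text": m.text,
        "type": m.entity_type,
        "groundings": [list(g) for g in m.groundings],
        "generic": m.generic,
        "modifications": [_mod_to_dict(x) for x in m.modifications],
    }


def to_standoff(
    doc_id: str,
    mentions: Sequence[EntityMention],
    events: Sequence[EventMention],
) -> dict:
    mention_ids: dict[int, str] = {}
    out_mentions = []
    for m in mentions:
        mid = f"M{len(out_mentions)}"
        mention_ids[id(m)] = mid
        d = _mention_to_dict(m)
        d["id"] = mid
        out_mentions.append(d)

    event_ids: dict[int, str] = {}
    out_events: list[dict] = []

    def emit_event(ev: EventMention) -> str:
        if id(ev) in event_ids:
            return event_ids[id(ev)]
        args: dict[str, list] = {}
        for role, vals in ev.arguments.items():
            refs = []
            for a in vals:
                if isinstance(a, EntityMention):
                    if id(a) not in mention_ids:
                        mid = f"M{len(out_mentions)}"
                        mention_ids[id(a)] = mid
                        d = _mention_to_dict(a)
                        d["id"] = mid
                        out_mentions.append(d)
                    refs.append({"mention": mention_ids[id(a)]})
                else:
                    refs.append({"event": emit_event(a)})
            args[role] = refs
        eid = f"E{len(out_events)}"
        event_ids[id(ev)] = eid
        out_events.append(
            {
                "id": eid,
                "sent": ev.sent_index,
                "label": ev.label,
                "trigger": list(ev.trigger),
                "trigger_text": ev.trigger_text,
                "sign": ev.sign,
                "negated": ev.negated,
                "coref": ev.coref,
                "rule": ev.rule,
                "args": args,
            }
        )
        return eid

    top = [emit_event(ev) for ev in events]
    return {
        "doc_id": doc_id,
        "mentions": out_mentions,
        "events": out_events,
        "top_events": top,
    }


def validate_standoff(data: dict) -> None:
    if not isinstance(data, dict):
        raise SchemaError("document must be an object")
    for key in ("doc_id", "mentions", "events"):
        if key not in data:
            raise SchemaError(f"missing key {key!r}")
    mention_ids = set()
    for m in data["mentions"]:
        for key in ("id", "sent", "span", "text", "type"):
            if key not in m:
                raise SchemaError(f"mention missing {key!r}")
        mention_ids.add(m["id"])
    event_ids = {e.get("id") for e in data["events"]}
    for e in data["events"]:
        for key in ("id", "sent", "label", "trigger", "args"):
            if key not in e:
                raise SchemaError(f"event missing {key!r}")
        for role, refs in e["args"].items():
            for ref in refs:
                if "mention" in ref:
                    if ref["mention"] not in mention_ids:
                        raise SchemaError(f"dangling mention ref in {e['id']}/{role}")
                elif "event" in ref:
                    if ref["event"] not in event_ids:
                        raise SchemaError(f"dangling event ref in {e['id']}/{role}")
                else:
                    raise SchemaError(f"bad argument ref in {e['id']}/{role}")


def from_standoff(data: dict) -> tuple[list[EntityMention], list[EventMention]]:
    validate_standoff(data)
    doc_id = data["doc_id"]
    mentions: dict[str, EntityMention] = {}
    for m in data["mentions"]:
        mentions[m["id"]] = EntityMention(
            doc_id=doc_id,
            sent_index=m["sent"],
            start=m["span"][0],
            end=m["span"][1],
            text=m["text"],
            entity_type=m["type"],
            groundings=[tuple(g) for g in m.get("groundings", [])],
            modifications=[
                Modification(
                    kind=x["kind"], subtype=x.get("subtype"),
                    variant=x.get("variant"), site=x.get("site"),
                    evidence=tuple(x["evidence"]) if x.get("evidence") else None,
                )
                for x in m.get("modifications", [])
            ],
            generic=m.get("generic", False),
        )
    raw_events = {e["id"]: e for e in data["events"]}
    built: dict[str, EventMention] = {}

    def build(eid: str, stack: tuple = ()) -> EventMention:
        if eid in built:
            return built[eid]
        if eid in stack:
            raise SchemaError(f"cyclic event nesting at {eid}")
        e = raw_events[eid]
        args: dict[str, list] = {}
        for role, refs in e["args"].items():
            vals = []
            for ref in refs:
                if "mention" in ref:
                    vals.append(mentions[ref["mention"]])
                else:
                    vals.append(build(ref["event"], stack + (eid,)))
            args[role] = vals
        ev = EventMention(
            doc_id=doc_id,
            sent_index=e["sent"],
            label=e["label"],
            trigger=tuple(e["trigger"]),
            trigger_text=e.get("trigger_text", ""),
            arguments=args,
            sign=e.get("sign", 1),
            negated=e.get("negated", False),
            rule=e.get("rule", ""),
            coref=e.get("coref", False),
        )
        built[eid] = ev
        return ev

    top = data.get("top_events") or list(raw_events)
    events = [build(eid) for eid in top]
    return list(mentions.values()), events


def dump(data: dict, fh) -> None:
    json.dump(data, fh, indent=1, ensure_ascii=False)


def load(fh) -> dict:
    return json.load(fh)
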