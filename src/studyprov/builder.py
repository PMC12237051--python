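"""The provenance builder.

Capturers emit one JSON *event* per modeler activity. The builder parses
each event, matches it against the activity type's provenance pattern, and
— if valid — chains it into the single study graph: the activity node is
always new; used products attach to the latest existing version (or
bootstrap version 1 for externally produced artifacts); generated products
become the next version of their identity; agents are deduplicated on
(name, version). Invalid events are discarded whole and recorded verbatim
in an error log. Ingestion is atomic per event and idempotent per
``event_id``.

Event JSON schema (top-level keys)::

    {
      "event_id": "...", "event_type": "specifying_simulation_experiment",
      "timestamp": "2024-01-01T00:00:00Z",
      "agent": {"name": "...", "version": "..."},
      "used": [{"entity_type": "...", "name": "...", "path": "..."}],
      "generated": [{"entity_type": "...", "name": "...", "path": "...",
                     "content": "...", "content_hash": "..."}]
    }

Unknown top-level keys are preserved in ``extras``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Iterable, Optional

from .model import (
    ActivityNode,
    ActivityType,
    EntityType,
    CycleError,
    DependencyEdge,
    EdgeKind,
    EntityIdentity,
    EntityVersion,
    ProvGraph,
    UnknownNodeError,
    activity_node_id,
    add_edge_checked,
    resolve_latest,
)
from .patterns import (
    MatchResult,
    MatchViolation,
    PatternSet,
    default_patterns,
    match_activity,
)

__all__ = [
    "EntityDescriptor",
    "AgentDescriptor",
    "Event",
    "ErrorLogRecord",
    "BuilderState",
    "EventError",
    "MalformedEventError",
    "MissingFieldError",
    "DuplicateEventError",
    "InvalidAttributeError",
    "parse_event",
    "ingest_event",
    "ingest_jsonl",
    "chain",
    "add_manual_dependency",
    "fill_attribute",
]

logger = logging.getLogger("studyprov.builder")

DEFAULT_MAX_CONTENT_BYTES = 1 << 20  # payloads above this keep only their hash


class EventError(Exception):
    pass


class MalformedEventError(EventError):
    """The event text is not valid JSON (or not a JSON object)."""


class MissingFieldError(EventError):
    """A structurally required field is absent."""


class DuplicateEventError(EventError):
    """This event_id was already processed; state is unchanged."""


class InvalidAttributeError(EventError):
    """A required attribute may not be blanked."""


@dataclass
class EntityDescriptor:
    """One entity reference inside an event."""

    entity_type: str
    name: str
    path: str
    content: Optional[str] = None
    content_hash: Optional[str] = None
    attrs: dict = field(default_factory=dict)  # additional descriptor keys

    @classmethod
    def from_dict(cls, raw: dict) -> "EntityDescriptor":
        if not isinstance(raw, dict):
            raise MissingFieldError(f"entity descriptor must be an object: {raw!r}")
        for key in ("entity_type", "name", "path"):
            if key not in raw:
                raise MissingFieldError(f"entity descriptor lacks {key!r}: {raw!r}")
        extra = {
            k: v
            for k, v in raw.items()
            if k not in ("entity_type", "name", "path", "content", "content_hash")
        }
        return cls(
            entity_type=raw["entity_type"],
            name=raw["name"],
            path=raw["path"],
            content=raw.get("content"),
            content_hash=raw.get("content_hash"),
            attrs=extra,
        )

    def to_dict(self) -> dict:
        out = {"entity_type": self.entity_type, "name": self.name, "path": self.path}
        if self.content is not None:
            out["content"] = self.content
        if self.content_hash is not None:
            out["content_hash"] = self.content_hash
        out.update(self.attrs)
        return out

    def match_attributes(self) -> dict:
        attrs = {"name": self.name, "path": self.path}
        attrs.update(self.attrs)
        if self.content is not None:
            attrs["content"] = self.content
        if self.content_hash is not None:
            attrs["content_hash"] = self.content_hash
        return attrs


@dataclass
class AgentDescriptor:
    name: str
    version: Optional[str] = None

    @classmethod
    def from_dict(cls, raw: dict) -> "AgentDescriptor":
        if not isinstance(raw, dict) or "name" not in raw:
            raise MissingFieldError(f"agent descriptor needs a 'name': {raw!r}")
        return cls(name=raw["name"], version=raw.get("version"))

    def to_dict(self) -> dict:
        out = {"name": self.name}
        if self.version is not None:
            out["version"] = self.version
        return out


@dataclass
class Event:
    """One captured modeler action, the unit of ingestion."""

    event_id: str
    event_type: str
    timestamp: str = ""
    agent: Optional[AgentDescriptor] = None
    used: list = field(default_factory=list)
    generated: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "event_id": self.event_id,
            "event_type": self.event_type,
            "timestamp": self.timestamp,
            "used": [d.to_dict() for d in self.used],
            "generated": [d.to_dict() for d in self.generated],
        }
        if self.agent is not None:
            out["agent"] = self.agent.to_dict()
        out.update(self.extras)
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


_TOP_LEVEL = {"event_id", "event_type", "timestamp", "agent", "used", "generated"}


def parse_event(json_text: str) -> Event:
    """Parse one event from JSON text.

    Raises :class:`MalformedEventError` for broken JSON and
    :class:`MissingFieldError` when ``event_id``, ``event_type`` or the
    ``generated`` list is absent. Both conditions are meant to be caught
    by ingestion fronts and turned into error-log records, never crashes.
    """
    try:
        raw = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise MalformedEventError(f"malformed JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise MalformedEventError("event must be a JSON object")
    for key in ("event_id", "event_type", "generated"):
        if key not in raw:
            raise MissingFieldError(f"event lacks required field {key!r}")
    agent = AgentDescriptor.from_dict(raw["agent"]) if "agent" in raw else None
    return Event(
        event_id=str(raw["event_id"]),
        event_type=str(raw["event_type"]),
        timestamp=str(raw.get("timestamp", "")),
        agent=agent,
        used=[EntityDescriptor.from_dict(d) for d in raw.get("used", [])],
        generated=[EntityDescriptor.from_dict(d) for d in raw["generated"]],
        extras={k: v for k, v in raw.items() if k not in _TOP_LEVEL},
    )


@dataclass
class ErrorLogRecord:
    """A rejected event, kept verbatim for inspection."""

    event_text: str  # byte-faithful original serialization
    violations: tuple
    received_at: str
    event_id: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "event": self.event_text,
            "violations": [v.to_dict() for v in self.violations],
            "received_at": self.received_at,
        }


def _utc_now() -> str:
    return datetime.now(timezone.utc).isoformat()


@dataclass
class BuilderState:
    """Graph + patterns + error log + dedup set of one builder instance."""

    graph: ProvGraph = field(default_factory=ProvGraph)
    patterns: PatternSet = field(default_factory=default_patterns)
    error_log: list = field(default_factory=list)
    processed_event_ids: set = field(default_factory=set)
    max_content_bytes: int = DEFAULT_MAX_CONTENT_BYTES
    strict: bool = True
    clock: Callable[[], str] = _utc_now
    _last_timestamp: str = ""

    def check_conservation(self) -> bool:
        return (
            len(self.graph.insertion_order) + len(self.error_log)
            == len(self.processed_event_ids)
        )


def _content_attributes(desc: EntityDescriptor, max_bytes: int) -> dict:
    """Attribute dict for a new version; large content degrades to hash."""
    attrs = {"name": desc.name, "path": desc.path}
    attrs.update({k: str(v) for k, v in desc.attrs.items()})
    content, chash = desc.content, desc.content_hash
    if content is not None:
        if chash is None:
            chash = hashlib.sha256(content.encode("utf-8")).hexdigest()
        if len(content.encode("utf-8")) <= max_bytes:
            attrs["content"] = content
    if chash is not None:
        attrs["content_hash"] = chash
    return attrs


def chain(
    graph: ProvGraph,
    event: Event,
    max_content_bytes: int = DEFAULT_MAX_CONTENT_BYTES,
) -> ProvGraph:
    """Chain one *already validated* event into the graph.

    The activity node is always new. Used descriptors resolve to the
    latest version of their identity; a used product never seen before
    bootstraps as version 1 (externally produced artifact). Generated
    descriptors create the next version (with a REVISION_OF edge when a
    predecessor exists). The agent is resolved or created once.
    """
    atype = ActivityType.parse(event.event_type)
    act = ActivityNode(
        activity_type=atype,
        timestamp=event.timestamp,
        node_id=activity_node_id(event.event_id),
        source_event_id=event.event_id,
    )
    graph.add_activity(act)

    seen_used = set()
    for desc in event.used:
        identity = EntityIdentity(EntityType.parse(desc.entity_type), desc.path, desc.name)
        if identity.key in seen_used:
            continue
        seen_used.add(identity.key)
        version = resolve_latest(graph, identity)
        if version is None:
            version = graph.new_version(identity, _content_attributes(desc, max_content_bytes))
        add_edge_checked(
            graph, DependencyEdge(EdgeKind.USED, act.node_id, version.node_id)
        )

    for desc in event.generated:
        identity = EntityIdentity(EntityType.parse(desc.entity_type), desc.path, desc.name)
        version = graph.new_version(identity, _content_attributes(desc, max_content_bytes))
        add_edge_checked(
            graph, DependencyEdge(EdgeKind.GENERATED_BY, version.node_id, act.node_id)
        )

    if event.agent is not None:
        agent = graph.resolve_agent(event.agent.name, event.agent.version)
        add_edge_checked(
            graph, DependencyEdge(EdgeKind.ASSOCIATED_WITH, act.node_id, agent.node_id)
        )
    return graph


def _match_event(state: BuilderState, event: Event) -> MatchResult:
    used = [(d.entity_type, d.match_attributes()) for d in event.used]
    generated = [(d.entity_type, d.match_attributes()) for d in event.generated]
    agent = None
    if event.agent is not None:
        attrs = {"name": event.agent.name}
        if event.agent.version is not None:
            attrs["version"] = event.agent.version
        agent = (event.agent.name, attrs)
    return match_activity(
        state.patterns, event.event_type, used, generated, agent, strict=state.strict
    )


def ingest_event(state: BuilderState, event: Event) -> BuilderState:
    """Process one parsed event: validate, then chain or log the rejection.

    The graph is extended only for valid events (atomic: rejected events
    contribute nothing). Replaying an already-processed ``event_id``
    raises :class:`DuplicateEventError` and changes nothing.
    """
    if event.event_id in state.processed_event_ids:
        raise DuplicateEventError(f"event {event.event_id!r} already processed")
    if event.timestamp and state._last_timestamp and event.timestamp < state._last_timestamp:
        logger.warning(
            "event %s has out-of-order timestamp %s (previous %s); "
            "insertion order is authoritative",
            event.event_id, event.timestamp, state._last_timestamp,
        )
    result = _match_event(state, event)
    if result.valid:
        try:
            chain(state.graph, event, state.max_content_bytes)
            logger.info("event %s accepted (%s)", event.event_id, event.event_type)
        except CycleError as exc:
            result = MatchResult(
                violations=(MatchViolation("cycle-violation", str(exc)),)
            )
    if not result.valid:
        state.error_log.append(
            ErrorLogRecord(
                event_text=event.to_json(),
                violations=result.violations,
                received_at=state.clock(),
                event_id=event.event_id,
            )
        )
        logger.info(
            "event %s rejected: %s",
            event.event_id,
            "; ".join(v.code for v in result.violations),
        )
    state.processed_event_ids.add(event.event_id)
    if event.timestamp:
        state._last_timestamp = max(state._last_timestamp, event.timestamp)
    return state


def ingest_jsonl(state: BuilderState, lines: Iterable[str]) -> BuilderState:
    """Ingest an offline event log, one JSON event per line.

    Malformed or field-incomplete lines become error-log records (with a
    positional surrogate id so conservation still holds); duplicates are
    logged and skipped.
    """
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            event = parse_event(line)
        except (MalformedEventError, MissingFieldError) as exc:
            surrogate = f"line-{lineno}-{hashlib.sha1(line.encode()).hexdigest()[:8]}"
            state.error_log.append(
                ErrorLogRecord(
                    event_text=line,
                    violations=(MatchViolation("malformed-event", str(exc)),),
                    received_at=state.clock(),
                    event_id=surrogate,
                )
            )
            state.processed_event_ids.add(surrogate)
            continue
        try:
            ingest_event(state, event)
        except DuplicateEventError:
            logger.warning("line %d: duplicate event %s skipped", lineno, event.event_id)
    return state


def add_manual_dependency(
    state: BuilderState,
    activity_id: str,
    entity_node_id: str,
    kind: EdgeKind = EdgeKind.USED,
) -> BuilderState:
    """Add a modeler-supplied USED edge (e.g., to make a model-adaptation
    relation explicit when no capturer could infer it).

    The edge is flagged ``origin="manual"`` in exports. Duplicating an
    existing edge is a warned no-op; a cycle-closing edge is rejected with
    the state unchanged.
    """
    if kind != EdgeKind.USED:
        raise EdgeKindNotManual(kind)
    for nid in (activity_id, entity_node_id):
        if nid not in state.graph:
            raise UnknownNodeError(f"no node with id {nid!r}")
    if state.graph.has_edge(EdgeKind.USED, activity_id, entity_node_id):
        warnings.warn(
            f"manual edge {activity_id}->{entity_node_id} duplicates an existing "
            "dependency; ignored",
            stacklevel=2,
        )
        return state
    add_edge_checked(
        state.graph,
        DependencyEdge(EdgeKind.USED, activity_id, entity_node_id, origin="manual"),
    )
    return state


class EdgeKindNotManual(EventError):
    def __init__(self, kind):
        super().__init__(f"only USED edges may be added manually, not {kind}")


def fill_attribute(state: BuilderState, node_id: str, key: str, value: str) -> BuilderState:
    """Manually fill a missing/blank attribute on an entity version (or the
    version string of an agent). Required attributes must stay non-empty."""
    node = state.graph.node(node_id)  # raises UnknownNodeError
    if node.kind == "entity":
        if key in ("name", "path") and not value:
            raise InvalidAttributeError(f"required attribute {key!r} must be non-empty")
        node.attributes[key] = value
    elif node.kind == "agent":
        if key != "version":
            raise InvalidAttributeError(
                "agent identity is (name, version); only 'version' is fillable"
            )
        node.version = value
    else:
        raise InvalidAttributeError("attributes can be filled on entities and agents only")
    return state
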