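"""Typed provenance graph for simulation studies.

The data model is a PROV-DM extension: *entities* are the products of a
simulation study (research questions, assumptions, simulation models,
experiment specifications, simulation data, scripts, visualizations, ...),
*activities* are the modeler's actions that use and generate them, and
*agents* are the software systems bearing responsibility for activities.
Dependencies form a directed acyclic graph.

Entities are versioned: every edit of a study product creates a new,
immutable :class:`EntityVersion` node, linked to its predecessor by a
``REVISION_OF`` edge, so that later dependencies can attach to the latest
version. Identity of an evolving product is the pair
``(entity type, canonical file path)``.

Node ids are deterministic functions of stable keys (event id for
activities, identity+version for entities, name+version for agents), so
rebuilding a graph from the same event stream reproduces identical ids and
byte-identical exports.
"""

from __future__ import annotations

import hashlib
import posixpath
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional, Union

import networkx as nx

__all__ = [
    "EntityType",
    "ActivityType",
    "EntityIdentity",
    "EntityVersion",
    "ActivityNode",
    "AgentNode",
    "EdgeKind",
    "DependencyEdge",
    "ProvGraph",
    "ProvError",
    "CycleError",
    "EdgeTypingError",
    "DuplicateEdgeError",
    "UnknownNodeError",
    "canonical_path",
    "resolve_latest",
    "add_edge_checked",
    "revalidate",
]


class ProvError(Exception):
    """Base class for provenance-graph errors."""


class CycleError(ProvError):
    """Adding the edge would close a directed cycle."""


class EdgeTypingError(ProvError):
    """Edge endpoints do not fit the edge kind's typing rule."""


class DuplicateEdgeError(ProvError):
    """An identical (kind, source, target) edge already exists."""


class UnknownNodeError(ProvError):
    """A referenced node id is not present in the graph."""


class EntityType(str, Enum):
    """Closed enumeration of simulation-study products.

    The conceptual model comprises ResearchQuestion, Requirement,
    Assumption, QualitativeModel, Data and Reference; the executable side
    comprises SimulationModel, SimulationExperiment and SimulationData;
    postprocessing adds Script and Visualization.
    """

    RESEARCH_QUESTION = "ResearchQuestion"
    REQUIREMENT = "Requirement"
    ASSUMPTION = "Assumption"
    QUALITATIVE_MODEL = "QualitativeModel"
    DATA = "Data"
    REFERENCE = "Reference"
    SIMULATION_MODEL = "SimulationModel"
    SIMULATION_EXPERIMENT = "SimulationExperiment"
    SIMULATION_DATA = "SimulationData"
    SCRIPT = "Script"
    VISUALIZATION = "Visualization"

    @classmethod
    def parse(cls, label: str) -> "EntityType":
        """Parse a label, tolerating snake_case / spaced variants.

        ``"research objective"`` is accepted as an alias for
        :attr:`RESEARCH_QUESTION` (both terms are in circulation for the
        same conceptual-model product).
        """
        key = _normalize_label(label)
        try:
            return _ENTITY_LABELS[key]
        except KeyError:
            raise ValueError(f"unknown entity type: {label!r}") from None


class ActivityType(str, Enum):
    """Closed enumeration of the eight modeler activities."""

    SPECIFYING_REFERENCE = "SpecifyingReference"
    SPECIFYING_RESEARCH_QUESTION = "SpecifyingResearchQuestion"
    SPECIFYING_REQUIREMENT = "SpecifyingRequirement"
    SPECIFYING_ASSUMPTION = "SpecifyingAssumption"
    SPECIFYING_SIMULATION_MODEL = "SpecifyingSimulationModel"
    SPECIFYING_SIMULATION_EXPERIMENT = "SpecifyingSimulationExperiment"
    EXECUTING_SIMULATION_EXPERIMENT = "ExecutingSimulationExperiment"
    ANALYZING_SIMULATION_DATA = "AnalyzingSimulationData"

    @property
    def event_name(self) -> str:
        """snake_case name used as ``event_type`` in capture events."""
        return _ACTIVITY_EVENT_NAMES[self]

    @classmethod
    def parse(cls, label: str) -> "ActivityType":
        key = _normalize_label(label)
        try:
            return _ACTIVITY_LABELS[key]
        except KeyError:
            raise ValueError(f"unknown activity type: {label!r}") from None


def _normalize_label(label: str) -> str:
    return "".join(ch for ch in str(label).casefold() if ch.isalnum())


_ENTITY_LABELS = {_normalize_label(t.value): t for t in EntityType}
_ENTITY_LABELS[_normalize_label("ResearchObjective")] = EntityType.RESEARCH_QUESTION

_ACTIVITY_LABELS = {_normalize_label(t.value): t for t in ActivityType}

_ACTIVITY_EVENT_NAMES = {
    ActivityType.SPECIFYING_REFERENCE: "specifying_reference",
    ActivityType.SPECIFYING_RESEARCH_QUESTION: "specifying_research_question",
    ActivityType.SPECIFYING_REQUIREMENT: "specifying_requirement",
    ActivityType.SPECIFYING_ASSUMPTION: "specifying_assumption",
    ActivityType.SPECIFYING_SIMULATION_MODEL: "specifying_simulation_model",
    ActivityType.SPECIFYING_SIMULATION_EXPERIMENT: "specifying_simulation_experiment",
    ActivityType.EXECUTING_SIMULATION_EXPERIMENT: "executing_simulation_experiment",
    ActivityType.ANALYZING_SIMULATION_DATA: "analyzing_simulation_data",
}


def canonical_path(path: str) -> str:
    """Normalize a file path into the identity form.

    Separators become ``/``, redundant segments (``.``, ``a/../``) are
    collapsed, case is preserved. The path is *not* resolved against any
    filesystem: identity is purely lexical.
    """
    p = str(path).replace("\\", "/")
    p = posixpath.normpath(p)
    return p


def _short_hash(s: str) -> str:
    return hashlib.sha1(s.encode("utf-8")).hexdigest()[:12]


@dataclass(frozen=True)
class EntityIdentity:
    """Identity key of an evolving study product: (entity type, path)."""

    entity_type: Union[EntityType, str]  # str only for foreign (untyped) imports
    path: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", canonical_path(self.path))

    @property
    def key(self) -> tuple:
        et = self.entity_type
        return (et.value if isinstance(et, EntityType) else str(et), self.path)

    @property
    def type_label(self) -> str:
        et = self.entity_type
        return et.value if isinstance(et, EntityType) else str(et)


def entity_node_id(identity: EntityIdentity, version: int) -> str:
    return f"ent-{_short_hash(identity.type_label + '|' + identity.path)}-v{version}"


def activity_node_id(event_id: str) -> str:
    return f"act-{_short_hash(str(event_id))}"


def agent_node_id(name: str, version: Optional[str]) -> str:
    return f"agt-{_short_hash(name + '|' + (version or ''))}"


@dataclass
class EntityVersion:
    """One immutable version of a study product.

    ``attributes`` always carries non-empty ``name`` and ``path``;
    ``specification``/``content`` and ``content_hash`` are optional.
    """

    identity: EntityIdentity
    version: int
    attributes: dict = field(default_factory=dict)
    node_id: str = ""

    def __post_init__(self) -> None:
        if self.version < 1:
            raise ValueError("version numbers start at 1")
        if not self.node_id:
            self.node_id = entity_node_id(self.identity, self.version)
        self.attributes.setdefault("name", self.identity.name or self.identity.path)
        self.attributes.setdefault("path", self.identity.path)

    @property
    def kind(self) -> str:
        return "entity"


@dataclass
class ActivityNode:
    """One validated modeler activity.

    ``member_activity_ids``/``count`` are populated only on aggregate nodes
    produced by chain aggregation (see :mod:`studyprov.views`).
    """

    activity_type: ActivityType
    timestamp: str
    node_id: str
    source_event_id: str
    member_activity_ids: tuple = ()
    count: int = 1

    @property
    def kind(self) -> str:
        return "activity"


@dataclass
class AgentNode:
    """A software system responsible for activities; identity (name, version)."""

    name: str
    version: Optional[str] = None
    node_id: str = ""

    def __post_init__(self) -> None:
        if not self.node_id:
            self.node_id = agent_node_id(self.name, self.version)

    @property
    def kind(self) -> str:
        return "agent"


class EdgeKind(str, Enum):
    USED = "USED"                      # activity -> entity version
    GENERATED_BY = "GENERATED_BY"      # entity version -> activity
    ASSOCIATED_WITH = "ASSOCIATED_WITH"  # activity -> agent
    REVISION_OF = "REVISION_OF"        # entity v(k+1) -> v(k), same identity


# kind -> (source node kind, target node kind)
_EDGE_TYPING = {
    EdgeKind.USED: ("activity", "entity"),
    EdgeKind.GENERATED_BY: ("entity", "activity"),
    EdgeKind.ASSOCIATED_WITH: ("activity", "agent"),
    EdgeKind.REVISION_OF: ("entity", "entity"),
}


@dataclass(frozen=True)
class DependencyEdge:
    kind: EdgeKind
    source: str
    target: str
    origin: str = "auto"  # "auto" | "manual"


class ProvGraph:
    """The single growing acyclic provenance graph of one study.

    Thin wrapper around a :class:`networkx.DiGraph` holding typed node
    objects, plus an authoritative activity insertion order and a version
    index per entity identity.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()
        self.insertion_order: list[str] = []
        self._versions: dict[tuple, list[str]] = {}
        self.extras: dict = {}  # foreign statements preserved by import

    # -- node access -------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def node(self, node_id: str):
        try:
            return self._g.nodes[node_id]["obj"]
        except KeyError:
            raise UnknownNodeError(f"no node with id {node_id!r}") from None

    def nodes(self) -> Iterator:
        for nid in self._g.nodes:
            yield self._g.nodes[nid]["obj"]

    def entity_versions(self) -> list[EntityVersion]:
        return [n for n in self.nodes() if isinstance(n, EntityVersion)]

    def activities(self) -> list[ActivityNode]:
        return [self.node(nid) for nid in self.insertion_order]

    def agents(self) -> list[AgentNode]:
        return [n for n in self.nodes() if isinstance(n, AgentNode)]

    def edges(self) -> list[DependencyEdge]:
        out = []
        for u, v, data in self._g.edges(data=True):
            out.append(DependencyEdge(data["kind"], u, v, data.get("origin", "auto")))
        return out

    def has_edge(self, kind: EdgeKind, source: str, target: str) -> bool:
        data = self._g.get_edge_data(source, target)
        return data is not None and data["kind"] == kind

    # -- mutation ----------------------------------------------------

    def add_entity_version(self, ev: EntityVersion) -> EntityVersion:
        key = ev.identity.key
        chain = self._versions.setdefault(key, [])
        if ev.version != len(chain) + 1:
            raise ProvError(
                f"versions of {key} must be gapless: expected "
                f"{len(chain) + 1}, got {ev.version}"
            )
        for req in ("name", "path"):
            if not ev.attributes.get(req):
                raise ProvError(f"entity version requires non-empty {req!r}")
        self._g.add_node(ev.node_id, obj=ev)
        chain.append(ev.node_id)
        return ev

    def new_version(self, identity: EntityIdentity, attributes: dict) -> EntityVersion:
        """Create the next version of ``identity`` (1 if none exists yet)
        and, for versions > 1, the REVISION_OF edge to the predecessor."""
        prev = resolve_latest(self, identity)
        ev = EntityVersion(identity, (prev.version + 1) if prev else 1, dict(attributes))
        self.add_entity_version(ev)
        if prev is not None:
            add_edge_checked(self, DependencyEdge(EdgeKind.REVISION_OF, ev.node_id, prev.node_id))
        return ev

    def add_activity(self, act: ActivityNode) -> ActivityNode:
        if act.node_id in self._g:
            raise ProvError(f"activity {act.node_id} already present")
        self._g.add_node(act.node_id, obj=act)
        self.insertion_order.append(act.node_id)
        return act

    def resolve_agent(self, name: str, version: Optional[str] = None) -> AgentNode:
        """Return the agent node for (name, version), creating it once."""
        nid = agent_node_id(name, version)
        if nid in self._g:
            return self._g.nodes[nid]["obj"]
        agent = AgentNode(name=name, version=version, node_id=nid)
        self._g.add_node(nid, obj=agent)
        return agent

    def remove_edge(self, source: str, target: str) -> None:
        """Low-level removal (manual graph surgery; used by audits/tests)."""
        self._g.remove_edge(source, target)

    # -- queries -----------------------------------------------------

    def used_entities(self, activity_id: str) -> list[EntityVersion]:
        out = []
        for _, tgt, data in self._g.out_edges(activity_id, data=True):
            if data["kind"] == EdgeKind.USED:
                out.append(self.node(tgt))
        return out

    def generated_entities(self, activity_id: str) -> list[EntityVersion]:
        out = []
        for src, _, data in self._g.in_edges(activity_id, data=True):
            if data["kind"] == EdgeKind.GENERATED_BY:
                out.append(self.node(src))
        return out

    def agent_of(self, activity_id: str) -> Optional[AgentNode]:
        for _, tgt, data in self._g.out_edges(activity_id, data=True):
            if data["kind"] == EdgeKind.ASSOCIATED_WITH:
                return self.node(tgt)
        return None

    def generator_of(self, entity_node_id: str) -> Optional[ActivityNode]:
        for _, tgt, data in self._g.out_edges(entity_node_id, data=True):
            if data["kind"] == EdgeKind.GENERATED_BY:
                return self.node(tgt)
        return None

    def users_of(self, entity_node_id: str) -> list[ActivityNode]:
        out = []
        for src, _, data in self._g.in_edges(entity_node_id, data=True):
            if data["kind"] == EdgeKind.USED:
                out.append(self.node(src))
        return out

    def versions_of(self, identity: EntityIdentity) -> list[EntityVersion]:
        return [self.node(nid) for nid in self._versions.get(identity.key, [])]

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self._g)

    def reachable(self, source: str, target: str) -> bool:
        return nx.has_path(self._g, source, target)

    def to_networkx(self) -> nx.DiGraph:
        """A copy of the underlying digraph (edge attr ``kind``, ``origin``)."""
        return self._g.copy()

    def copy(self) -> "ProvGraph":
        g = ProvGraph()
        g._g = self._g.copy()
        # node objects are shared immutably except attributes dicts: deep-ish copy
        for nid in g._g.nodes:
            obj = g._g.nodes[nid]["obj"]
            if isinstance(obj, EntityVersion):
                obj = replace(obj, attributes=dict(obj.attributes))
                g._g.nodes[nid]["obj"] = obj
        g.insertion_order = list(self.insertion_order)
        g._versions = {k: list(v) for k, v in self._versions.items()}
        g.extras = dict(self.extras)
        return g

    def stats(self) -> dict:
        edges = self.edges()
        return {
            "entity_versions": len(self.entity_versions()),
            "activities": len(self.insertion_order),
            "agents": len(self.agents()),
            "edges": len(edges),
            "used": sum(e.kind == EdgeKind.USED for e in edges),
            "generated_by": sum(e.kind == EdgeKind.GENERATED_BY for e in edges),
            "associated_with": sum(e.kind == EdgeKind.ASSOCIATED_WITH for e in edges),
            "revision_of": sum(e.kind == EdgeKind.REVISION_OF for e in edges),
        }


# -- module-level operations ------------------------------------------


def resolve_latest(graph: ProvGraph, identity: EntityIdentity) -> Optional[EntityVersion]:
    """Latest version of ``identity`` in ``graph``, or ``None`` if absent.

    Dependencies of new activities always attach here: each edit creates a
    new version, so the maximal version number is the current state of the
    product.
    """
    chain = graph._versions.get(identity.key)
    if not chain:
        return None
    return graph.node(chain[-1])


def add_edge_checked(graph: ProvGraph, edge: DependencyEdge) -> ProvGraph:
    """Insert ``edge`` iff endpoints exist, typing is legal, it is not a
    duplicate, and no directed cycle results. The graph is never left
    half-modified: all checks precede the single mutation."""
    for nid in (edge.source, edge.target):
        if nid not in graph:
            raise UnknownNodeError(f"edge endpoint {nid!r} not in graph")
    src_kind, tgt_kind = _EDGE_TYPING[edge.kind]
    src, tgt = graph.node(edge.source), graph.node(edge.target)
    if src.kind != src_kind or tgt.kind != tgt_kind:
        raise EdgeTypingError(
            f"{edge.kind.value} requires {src_kind}->{tgt_kind}, "
            f"got {src.kind}->{tgt.kind}"
        )
    if edge.kind == EdgeKind.REVISION_OF:
        if src.identity.key != tgt.identity.key or src.version != tgt.version + 1:
            raise EdgeTypingError(
                "REVISION_OF must link consecutive versions of one identity"
            )
    if graph._g.has_edge(edge.source, edge.target):
        existing = graph._g.get_edge_data(edge.source, edge.target)["kind"]
        if existing == edge.kind:
            raise DuplicateEdgeError(
                f"duplicate edge {edge.kind.value} {edge.source}->{edge.target}"
            )
        raise EdgeTypingError("conflicting edge kinds between one node pair")
    if edge.source == edge.target or (
        edge.target in graph._g and nx.has_path(graph._g, edge.target, edge.source)
    ):
        raise CycleError(
            f"edge {edge.source}->{edge.target} would close a directed cycle"
        )
    graph._g.add_edge(edge.source, edge.target, kind=edge.kind, origin=edge.origin)
    return graph


def revalidate(graph: ProvGraph, patterns) -> list:
    """Audit a stored graph: re-match every activity (with its incident
    USED/GENERATED_BY/ASSOCIATED_WITH context) against its pattern.

    Returns the concatenated violations, each prefixed with the activity
    node id; empty list iff the graph still satisfies all patterns.
    """
    from .patterns import match_activity  # local import to avoid cycle

    violations = []
    for act in graph.activities():
        used = [
            (ev.identity.entity_type, ev.attributes) for ev in graph.used_entities(act.node_id)
        ]
        generated = [
            (ev.identity.entity_type, ev.attributes)
            for ev in graph.generated_entities(act.node_id)
        ]
        agent = graph.agent_of(act.node_id)
        agent_arg = None
        if agent is not None:
            attrs = {"name": agent.name}
            if agent.version:
                attrs["version"] = agent.version
            agent_arg = (agent.name, attrs)
        result = match_activity(patterns, act.activity_type, used, generated, agent_arg)
        for v in result.violations:
            violations.append(replace(v, detail=f"{act.node_id}: {v.detail}"))
    return violations
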