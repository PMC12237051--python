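"""Serialization and reduction views of provenance graphs.

* PROV-JSON export/import (``entity``/``activity``/``agent`` sections with
  ``used``/``wasGeneratedBy``/``wasAssociatedWith`` relations; study-domain
  node types and the version relation are carried in a custom ``simprov:``
  namespace).
* DOT export (Graphviz text; PROV drawing convention: entities as
  ellipses, activities as rectangles, agents as houses).
* Two non-destructive reductions: *chain aggregation*, which collapses
  consecutive runs of the same activity type into one aggregate activity
  to reveal the phases of a study, and *transitive reduction*, which
  removes every dependency edge implied by a longer path.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from typing import Optional

import networkx as nx

from .model import (
    ActivityNode,
    ActivityType,
    AgentNode,
    DependencyEdge,
    EdgeKind,
    EntityIdentity,
    EntityType,
    EntityVersion,
    ProvGraph,
)

__all__ = [
    "ReducedGraph",
    "ProvJsonError",
    "MalformedDocumentError",
    "UnknownTypeError",
    "export_prov_json",
    "import_prov_json",
    "aggregate_chains",
    "transitive_reduce",
    "export_dot",
]

SIMPROV_NS = "https://studyprov.dev/ns/simprov#"
PROV_NS = "http://www.w3.org/ns/prov#"

_KNOWN_SECTIONS = {
    "prefix",
    "entity",
    "activity",
    "agent",
    "used",
    "wasGeneratedBy",
    "wasAssociatedWith",
    "simprov:revisionOf",
}


class ProvJsonError(Exception):
    pass


class MalformedDocumentError(ProvJsonError):
    pass


class UnknownTypeError(ProvJsonError):
    pass


class ReducedGraph(ProvGraph):
    """A reduction view: same shape as :class:`ProvGraph`; aggregate
    activities carry ``member_activity_ids`` and ``count`` metadata.
    Reductions never invent nodes — every node maps to >= 1 original."""


def _rel_id(prefix: str, source: str, target: str) -> str:
    return f"_:{prefix}-{hashlib.sha1(f'{source}|{target}'.encode()).hexdigest()[:10]}"


# -- PROV-JSON ---------------------------------------------------------


def export_prov_json(graph: ProvGraph) -> str:
    """Serialize to PROV-JSON with deterministic key ordering.

    The same graph always yields byte-identical text, so replayed event
    streams can be compared by file diff.
    """
    entities, activities, agents = {}, {}, {}
    used, generated_by, associated, revisions = {}, {}, {}, {}

    for ev in graph.entity_versions():
        et = ev.identity.entity_type
        rec = {
            "prov:type": f"simprov:{et.value}" if isinstance(et, EntityType) else str(et),
            "simprov:name": ev.attributes.get("name", ""),
            "simprov:path": ev.attributes.get("path", ""),
            "simprov:version": ev.version,
        }
        for key, value in sorted(ev.attributes.items()):
            if key in ("name", "path"):
                continue
            rec[f"simprov:attr:{key}"] = value
        entities[ev.node_id] = rec

    for order, act_id in enumerate(graph.insertion_order):
        act = graph.node(act_id)
        rec = {
            "prov:type": f"simprov:{act.activity_type.value}",
            "prov:startTime": act.timestamp,
            "simprov:event": act.source_event_id,
            "simprov:order": order,
        }
        if act.member_activity_ids:
            rec["simprov:members"] = list(act.member_activity_ids)
            rec["simprov:count"] = act.count
        activities[act_id] = rec

    for agent in graph.agents():
        rec = {"prov:type": "prov:SoftwareAgent", "simprov:name": agent.name}
        if agent.version is not None:
            rec["simprov:toolVersion"] = agent.version
        agents[agent.node_id] = rec

    for edge in graph.edges():
        if edge.kind == EdgeKind.USED:
            rec = {"prov:activity": edge.source, "prov:entity": edge.target}
            if edge.origin != "auto":
                rec["simprov:origin"] = edge.origin
            used[_rel_id("u", edge.source, edge.target)] = rec
        elif edge.kind == EdgeKind.GENERATED_BY:
            generated_by[_rel_id("g", edge.source, edge.target)] = {
                "prov:entity": edge.source,
                "prov:activity": edge.target,
            }
        elif edge.kind == EdgeKind.ASSOCIATED_WITH:
            associated[_rel_id("a", edge.source, edge.target)] = {
                "prov:activity": edge.source,
                "prov:agent": edge.target,
            }
        elif edge.kind == EdgeKind.REVISION_OF:
            revisions[_rel_id("r", edge.source, edge.target)] = {
                "simprov:newer": edge.source,
                "simprov:older": edge.target,
            }

    doc = {
        "prefix": {"prov": PROV_NS, "simprov": SIMPROV_NS},
        "entity": entities,
        "activity": activities,
        "agent": agents,
        "used": used,
        "wasGeneratedBy": generated_by,
        "wasAssociatedWith": associated,
        "simprov:revisionOf": revisions,
    }
    for section, content in sorted(graph.extras.get("foreign_sections", {}).items()):
        doc[section] = content
    return json.dumps(doc, indent=2, sort_keys=True)


def _strip_ns(label: str) -> str:
    return label.split(":", 1)[1] if label.startswith("simprov:") else label


def import_prov_json(text: str, strict: bool = True) -> ProvGraph:
    """Reconstruct a :class:`ProvGraph` from PROV-JSON text.

    The document must declare the ``simprov`` namespace. In strict mode an
    entity with a type outside the study taxonomy raises
    :class:`UnknownTypeError`; in permissive mode it is imported as an
    untyped (foreign-typed) entity with a warning. Foreign top-level
    sections are preserved in ``graph.extras`` and survive re-export.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedDocumentError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise MalformedDocumentError("document must be a JSON object")
    prefixes = doc.get("prefix", {})
    if "simprov" not in prefixes:
        raise MalformedDocumentError("document does not declare the simprov namespace")

    graph = ProvGraph()

    # entities, grouped by identity so versions insert in order
    parsed = []
    for node_id, rec in doc.get("entity", {}).items():
        raw_type = rec.get("prov:type", "")
        label = _strip_ns(raw_type)
        try:
            etype = EntityType.parse(label)
        except ValueError:
            if strict:
                raise UnknownTypeError(f"entity {node_id}: unknown type {raw_type!r}")
            warnings.warn(
                f"entity {node_id}: foreign type {raw_type!r} imported untyped",
                stacklevel=2,
            )
            etype = raw_type
        attrs = {
            "name": rec.get("simprov:name", ""),
            "path": rec.get("simprov:path", ""),
        }
        for key, value in rec.items():
            if key.startswith("simprov:attr:"):
                attrs[key[len("simprov:attr:"):]] = value
        version = int(rec.get("simprov:version", 1))
        identity = EntityIdentity(etype, attrs["path"], attrs["name"])
        parsed.append((identity, version, attrs, node_id))
    for identity, version, attrs, node_id in sorted(
        parsed, key=lambda item: (item[0].key, item[1])
    ):
        ev = EntityVersion(identity, version, attrs, node_id=node_id)
        _add_entity_version_raw(graph, ev)

    acts = []
    for node_id, rec in doc.get("activity", {}).items():
        label = _strip_ns(rec.get("prov:type", ""))
        try:
            atype = ActivityType.parse(label)
        except ValueError:
            raise UnknownTypeError(f"activity {node_id}: unknown type {label!r}")
        act = ActivityNode(
            activity_type=atype,
            timestamp=rec.get("prov:startTime", ""),
            node_id=node_id,
            source_event_id=rec.get("simprov:event", ""),
            member_activity_ids=tuple(rec.get("simprov:members", ())),
            count=int(rec.get("simprov:count", 1)),
        )
        acts.append((int(rec.get("simprov:order", 0)), act))
    for _, act in sorted(acts, key=lambda item: item[0]):
        graph.add_activity(act)

    for node_id, rec in doc.get("agent", {}).items():
        agent = AgentNode(
            name=rec.get("simprov:name", ""),
            version=rec.get("simprov:toolVersion"),
            node_id=node_id,
        )
        graph._g.add_node(node_id, obj=agent)

    def _edge(kind, src, tgt, origin="auto"):
        for nid in (src, tgt):
            if nid not in graph:
                raise MalformedDocumentError(f"relation references unknown node {nid!r}")
        graph._g.add_edge(src, tgt, kind=kind, origin=origin)

    for rec in doc.get("used", {}).values():
        _edge(
            EdgeKind.USED,
            rec["prov:activity"],
            rec["prov:entity"],
            rec.get("simprov:origin", "auto"),
        )
    for rec in doc.get("wasGeneratedBy", {}).values():
        _edge(EdgeKind.GENERATED_BY, rec["prov:entity"], rec["prov:activity"])
    for rec in doc.get("wasAssociatedWith", {}).values():
        _edge(EdgeKind.ASSOCIATED_WITH, rec["prov:activity"], rec["prov:agent"])
    for rec in doc.get("simprov:revisionOf", {}).values():
        _edge(EdgeKind.REVISION_OF, rec["simprov:newer"], rec["simprov:older"])

    foreign = {k: v for k, v in doc.items() if k not in _KNOWN_SECTIONS}
    if foreign:
        graph.extras["foreign_sections"] = foreign

    if not graph.is_acyclic():
        raise MalformedDocumentError("imported dependency graph contains a cycle")
    return graph


def _add_entity_version_raw(graph: ProvGraph, ev: EntityVersion) -> None:
    """Insert a version without the gapless-sequence check (views and
    imports may carry sparse version numbers)."""
    key = ev.identity.key
    chain = graph._versions.setdefault(key, [])
    graph._g.add_node(ev.node_id, obj=ev)
    chain.append(ev.node_id)
    chain.sort(key=lambda nid: graph.node(nid).version)


# -- chain aggregation -------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def aggregate_chains(graph: ProvGraph) -> ReducedGraph:
    """Collapse chains of same-type activities into aggregate activities.

    Two activities of the same type belong to one chain when the output of
    one feeds the other directly through entity versions only: either a
    generated version is used by the other activity, or the other
    activity's generated version is its direct revision. Entity versions
    that are purely internal to one aggregate (non-latest, generated and
    superseded within the group, never used outside it) are elided; the
    aggregate thus exposes the union of its external used-dependencies,
    its surviving (in particular final) generated versions, and all its
    agents. The view is non-destructive and idempotent.
    """
    order = list(graph.insertion_order)
    uf = _UnionFind(order)
    for act_id in order:
        act = graph.node(act_id)
        for ev in graph.generated_entities(act_id):
            # generated-then-used by a same-type activity
            for user in graph.users_of(ev.node_id):
                if user.activity_type == act.activity_type:
                    uf.union(act_id, user.node_id)
            # direct revision generated by a same-type activity
            chain_ids = graph._versions.get(ev.identity.key, [])
            for nid in chain_ids:
                succ = graph.node(nid)
                if succ.version == ev.version + 1:
                    gen = graph.generator_of(succ.node_id)
                    if gen is not None and gen.activity_type == act.activity_type:
                        uf.union(act_id, gen.node_id)

    groups: dict[str, list[str]] = {}
    for act_id in order:
        groups.setdefault(uf.find(act_id), []).append(act_id)

    # representative node per group, ordered by first member
    rep_of: dict[str, str] = {}
    rep_nodes: dict[str, ActivityNode] = {}
    ordered_groups = sorted(groups.values(), key=lambda ms: order.index(ms[0]))
    for members in ordered_groups:
        first = graph.node(members[0])
        if len(members) == 1 and first.count == 1 and not first.member_activity_ids:
            rep = ActivityNode(
                activity_type=first.activity_type,
                timestamp=first.timestamp,
                node_id=first.node_id,
                source_event_id=first.source_event_id,
            )
        else:
            member_ids = []
            total = 0
            for m in members:
                node = graph.node(m)
                member_ids.extend(node.member_activity_ids or (m,))
                total += node.count
            rep = ActivityNode(
                activity_type=first.activity_type,
                timestamp=first.timestamp,
                node_id="agg-" + hashlib.sha1("|".join(member_ids).encode()).hexdigest()[:12],
                source_event_id=first.source_event_id,
                member_activity_ids=tuple(member_ids),
                count=total,
            )
        for m in members:
            rep_of[m] = rep.node_id
        rep_nodes[rep.node_id] = rep

    multi = {rep_of[m] for ms in groups.values() if len(ms) > 1 for m in ms}

    def group_of_activity(act_id: Optional[str]) -> Optional[str]:
        return rep_of.get(act_id) if act_id else None

    # decide which entity versions are elided
    hidden: set[str] = set()
    for ev in graph.entity_versions():
        chain_ids = graph._versions.get(ev.identity.key, [])
        if chain_ids and chain_ids[-1] == ev.node_id:
            continue  # latest version always survives
        gen = graph.generator_of(ev.node_id)
        if gen is None:
            continue
        g = rep_of.get(gen.node_id)
        if g not in multi:
            continue
        users = graph.users_of(ev.node_id)
        if any(rep_of.get(u.node_id) != g for u in users):
            continue
        succ = next(
            (graph.node(nid) for nid in chain_ids if graph.node(nid).version == ev.version + 1),
            None,
        )
        if succ is None:
            continue
        succ_gen = graph.generator_of(succ.node_id)
        if succ_gen is None or rep_of.get(succ_gen.node_id) != g:
            continue
        hidden.add(ev.node_id)

    reduced = ReducedGraph()
    for ev in graph.entity_versions():
        if ev.node_id not in hidden:
            _add_entity_version_raw(
                reduced,
                EntityVersion(ev.identity, ev.version, dict(ev.attributes), node_id=ev.node_id),
            )
    for rep_id in [rep_of[ms[0]] for ms in ordered_groups]:
        reduced.add_activity(rep_nodes[rep_id])
    for agent in graph.agents():
        reduced._g.add_node(
            agent.node_id, obj=AgentNode(agent.name, agent.version, agent.node_id)
        )

    seen = set()

    def put(kind, src, tgt, origin="auto"):
        if src == tgt or (kind, src, tgt) in seen:
            return
        seen.add((kind, src, tgt))
        reduced._g.add_edge(src, tgt, kind=kind, origin=origin)

    for edge in graph.edges():
        if edge.kind == EdgeKind.REVISION_OF:
            if edge.source in hidden:
                continue
            tgt = edge.target
            while tgt in hidden:
                chain_ids = graph._versions[graph.node(tgt).identity.key]
                node = graph.node(tgt)
                older = [
                    nid for nid in chain_ids if graph.node(nid).version < node.version
                ]
                tgt = older[-1] if older else None
                if tgt is None:
                    break
            if tgt is not None:
                put(EdgeKind.REVISION_OF, edge.source, tgt, edge.origin)
        elif edge.kind == EdgeKind.USED:
            src = rep_of[edge.source]
            if edge.target in hidden:
                continue
            gen = graph.generator_of(edge.target)
            if gen is not None and rep_of.get(gen.node_id) == src and src in multi:
                continue  # in-group dependency: would self-refer through the aggregate
            put(EdgeKind.USED, src, edge.target, edge.origin)
        elif edge.kind == EdgeKind.GENERATED_BY:
            if edge.source in hidden:
                continue
            put(EdgeKind.GENERATED_BY, edge.source, rep_of[edge.target], edge.origin)
        elif edge.kind == EdgeKind.ASSOCIATED_WITH:
            put(EdgeKind.ASSOCIATED_WITH, rep_of[edge.source], edge.target, edge.origin)

    # Merging activities can, in pathological interleavings, close a cycle
    # through mutually dependent groups; coarsen by dropping the offending
    # usage edges (the member-level graph retains them).
    while not reduced.is_acyclic():
        cycle = nx.find_cycle(reduced._g)
        for u, v in cycle:
            if reduced._g.edges[u, v]["kind"] == EdgeKind.USED:
                reduced._g.remove_edge(u, v)
                break
        else:
            reduced._g.remove_edge(*cycle[0])

    return reduced


# -- transitive reduction ----------------------------------------------


def transitive_reduce(graph: ProvGraph) -> ReducedGraph:
    """The unique transitive reduction of the dependency DAG.

    Node set is unchanged; the surviving edge set is the minimal one with
    the same reachability relation. REVISION_OF edges are semantic (they
    are the version history, not redundancy) and are kept verbatim and
    excluded from the reduction.
    """
    work = nx.DiGraph()
    work.add_nodes_from(graph._g.nodes)
    revision_edges = []
    for edge in graph.edges():
        if edge.kind == EdgeKind.REVISION_OF:
            revision_edges.append(edge)
        else:
            work.add_edge(edge.source, edge.target)
    if not nx.is_directed_acyclic_graph(work):
        raise ValueError("transitive reduction requires an acyclic graph")
    minimal = nx.transitive_reduction(work)

    reduced = ReducedGraph()
    for ev in graph.entity_versions():
        _add_entity_version_raw(
            reduced,
            EntityVersion(ev.identity, ev.version, dict(ev.attributes), node_id=ev.node_id),
        )
    for act_id in graph.insertion_order:
        act = graph.node(act_id)
        reduced.add_activity(
            ActivityNode(
                act.activity_type,
                act.timestamp,
                act.node_id,
                act.source_event_id,
                act.member_activity_ids,
                act.count,
            )
        )
    for agent in graph.agents():
        reduced._g.add_node(
            agent.node_id, obj=AgentNode(agent.name, agent.version, agent.node_id)
        )
    for edge in graph.edges():
        if edge.kind == EdgeKind.REVISION_OF:
            continue
        if minimal.has_edge(edge.source, edge.target):
            reduced._g.add_edge(
                edge.source, edge.target, kind=edge.kind, origin=edge.origin
            )
    for edge in revision_edges:
        reduced._g.add_edge(edge.source, edge.target, kind=edge.kind, origin=edge.origin)
    return reduced


# -- DOT ---------------------------------------------------------------

_SHAPES = {"entity": "ellipse", "activity": "box", "agent": "house"}
_FILLS = {"entity": "khaki1", "activity": "lightblue2", "agent": "navajowhite"}


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def export_dot(graph: ProvGraph) -> str:
    """Graphviz DOT text with deterministic node/edge ordering.

    Entities are ellipses, activities rectangles, agents houses (the
    usual PROV drawing convention); manually added dependencies are drawn
    green and labelled; aggregate activities show their member count.
    """
    lines = ["digraph provenance {", "  rankdir=BT;"]
    nodes = sorted(graph.nodes(), key=lambda n: (n.kind, n.node_id))
    for node in nodes:
        if isinstance(node, EntityVersion):
            label = f"{node.attributes.get('name', '')}\\n{node.identity.type_label} v{node.version}"
        elif isinstance(node, ActivityNode):
            label = node.activity_type.value
            if node.count > 1:
                label += f"\\n(x{node.count})"
        else:
            label = node.name + (f"\\n{node.version}" if node.version else "")
        lines.append(
            f'  "{_dot_escape(node.node_id)}" [label="{_dot_escape(label)}", '
            f'shape={_SHAPES[node.kind]}, style=filled, fillcolor={_FILLS[node.kind]}];'
        )
    edges = sorted(graph.edges(), key=lambda e: (e.kind.value, e.source, e.target))
    for edge in edges:
        attrs = [f'label="{edge.kind.value.lower()}"']
        if edge.origin == "manual":
            attrs = ['label="manual"', 'color="forestgreen"', "penwidth=2"]
        elif edge.kind == EdgeKind.REVISION_OF:
            attrs.append("style=dashed")
        lines.append(
            f'  "{_dot_escape(edge.source)}" -> "{_dot_escape(edge.target)}" '
            f"[{', '.join(attrs)}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
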