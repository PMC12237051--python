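"""Synthetic event streams and graphs for testing every pipeline stage.

The generator emulates the lifecycle of a small simulation study in three
phase kinds:

* ``conceptual`` — specifying references, the research question,
  assumptions and requirements (4 events per iteration);
* ``refine`` — iterative development: each iteration edits the model,
  edits the experiment, executes it and analyzes the output
  (4 events per iteration, all revising the same four files);
* ``adapt`` — cloning the model under a new path, executing it and
  comparatively analyzing old vs new output (3 events per iteration). The
  clone's relation to the original is deliberately *not* captured — it is
  the canonical case for a manual dependency.

Streams are deterministic in ``(script, seed)``. With
``invalid_fraction > 0`` a seeded subset of events is corrupted using only
violation classes the pattern engine detects (required entity removed,
required attribute blanked, unknown activity type), and listed in a
manifest so the expected error log is exactly computable.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field
from typing import Optional

from .builder import AgentDescriptor, EntityDescriptor, Event
from .model import (
    ActivityNode,
    ActivityType,
    DependencyEdge,
    EdgeKind,
    EntityIdentity,
    EntityType,
    EntityVersion,
    ProvGraph,
    activity_node_id,
    add_edge_checked,
    resolve_latest,
)

__all__ = [
    "Phase",
    "StudyScript",
    "StreamBundle",
    "generate_stream",
    "fig2_stream",
    "random_graph",
]

_EDITOR = AgentDescriptor(name="code-editor", version="1.92")
_RUNNER = AgentDescriptor(name="sim-runner", version="2.1")
_ANALYST = AgentDescriptor(name="py-analysis", version="3.11")


@dataclass(frozen=True)
class Phase:
    kind: str  # "conceptual" | "refine" | "adapt"
    iterations: int = 1

    def __post_init__(self):
        if self.kind not in ("conceptual", "refine", "adapt"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass(frozen=True)
class StudyScript:
    phases: tuple
    seed: int = 0
    invalid_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        object.__setattr__(
            self,
            "phases",
            tuple(p if isinstance(p, Phase) else Phase(*p) for p in self.phases),
        )


@dataclass
class StreamBundle:
    """Events plus the sidecar manifest of corrupted event ids."""

    events: list
    manifest: dict


def _desc(etype: EntityType, name: str, path: str, content: Optional[str] = None) -> EntityDescriptor:
    return EntityDescriptor(
        entity_type=etype.value, name=name, path=path, content=content
    )


class _Emitter:
    def __init__(self, seed: int):
        self.n = 0
        self.seed = seed
        self.events: list[Event] = []

    def emit(self, event_type, agent, used, generated, **extras) -> Event:
        self.n += 1
        ev = Event(
            event_id=f"ev-{self.seed}-{self.n:04d}",
            event_type=event_type,
            timestamp=f"2024-01-01T{(self.n // 3600) % 24:02d}:{(self.n // 60) % 60:02d}:{self.n % 60:02d}Z",
            agent=agent,
            used=used,
            generated=generated,
            extras=extras,
        )
        self.events.append(ev)
        return ev


def generate_stream(script: StudyScript, patterns=None) -> StreamBundle:
    """Generate the deterministic event stream of one scripted study.

    ``patterns`` is accepted for symmetry with the builder interface;
    streams are valid by construction against the default pattern set, so
    the argument only matters when corrupting (the corruption classes are
    pattern-engine violation classes).
    """
    em = _Emitter(script.seed)
    spec = ActivityType.SPECIFYING_SIMULATION_MODEL.event_name
    for phase in script.phases:
        if phase.kind == "conceptual":
            for i in range(1, phase.iterations + 1):
                ref = _desc(
                    EntityType.REFERENCE,
                    f"source-paper-{i}",
                    f"refs/reference_paper{i}.pdf",
                    f"doi:10.0/demo.{script.seed}.{i}",
                )
                em.emit("specifying_reference", _EDITOR, [], [ref])
                question = _desc(
                    EntityType.RESEARCH_QUESTION,
                    f"question-{i}",
                    f"concept/question_{i}.md",
                    f"How does mechanism {i} shape the dynamics?",
                )
                em.emit("specifying_research_question", _EDITOR, [ref], [question])
                em.emit(
                    "specifying_assumption",
                    _EDITOR,
                    [ref],
                    [
                        _desc(
                            EntityType.ASSUMPTION,
                            f"assumption-{i}",
                            f"concept/assumption_{i}.md",
                            "particles are uniformly distributed",
                        )
                    ],
                )
                em.emit(
                    "specifying_requirement",
                    _EDITOR,
                    [question],
                    [
                        _desc(
                            EntityType.REQUIREMENT,
                            f"requirement-{i}",
                            f"concept/requirement_{i}.md",
                            "reproduce the published trajectories",
                        )
                    ],
                )
        elif phase.kind == "refine":
            for i in range(1, phase.iterations + 1):
                model = _desc(
                    EntityType.SIMULATION_MODEL,
                    "main-model",
                    "model_main.mlr",
                    f"rule_{i}: A + B -> C @ k{i}\n",
                )
                em.emit(spec, _EDITOR, [], [model])
                experiment = _desc(
                    EntityType.SIMULATION_EXPERIMENT,
                    "scan-experiment",
                    "experiment_scan.py",
                    f"scan(k{i}, runs=10)\n",
                )
                em.emit(
                    "specifying_simulation_experiment", _EDITOR, [model], [experiment]
                )
                data = _desc(
                    EntityType.SIMULATION_DATA,
                    "scan-output",
                    "out/simdata_run.csv",
                    f"t,x\n0,{i}\n",
                )
                em.emit(
                    "executing_simulation_experiment",
                    _RUNNER,
                    [experiment, model],
                    [data],
                )
                em.emit(
                    "analyzing_simulation_data",
                    _ANALYST,
                    [data],
                    [
                        _desc(
                            EntityType.VISUALIZATION,
                            "trajectory-plot",
                            "figs/vis_result.svg",
                            f"<svg><!-- iteration {i} --></svg>",
                        )
                    ],
                )
        elif phase.kind == "adapt":
            for i in range(1, phase.iterations + 1):
                adapted = _desc(
                    EntityType.SIMULATION_MODEL,
                    "adapted-model",
                    f"model_adapted_{i}.mlr",
                    f"rule_var: A + B -> C @ k_var{i}\n",
                )
                # the clone relation to the original model is not captured:
                # it is added manually by the modeler afterwards
                em.emit(spec, _EDITOR, [], [adapted])
                experiment = _desc(
                    EntityType.SIMULATION_EXPERIMENT, "scan-experiment", "experiment_scan.py"
                )
                data_adapted = _desc(
                    EntityType.SIMULATION_DATA,
                    "adapted-output",
                    f"out/simdata_adapted_{i}.csv",
                    f"t,x\n0,{-i}\n",
                )
                em.emit(
                    "executing_simulation_experiment",
                    _RUNNER,
                    [experiment, adapted],
                    [data_adapted],
                )
                em.emit(
                    "analyzing_simulation_data",
                    _ANALYST,
                    [
                        data_adapted,
                        _desc(EntityType.SIMULATION_DATA, "scan-output", "out/simdata_run.csv"),
                    ],
                    [
                        _desc(
                            EntityType.VISUALIZATION,
                            "comparison-plot",
                            f"figs/vis_comparison_{i}.svg",
                            f"<svg><!-- compare {i} --></svg>",
                        )
                    ],
                )

    manifest = {
        "seed": script.seed,
        "invalid_fraction": script.invalid_fraction,
        "n_events": len(em.events),
        "corrupted": [],
    }
    if script.invalid_fraction > 0 and em.events:
        rng = random.Random(script.seed)
        n_corrupt = round(script.invalid_fraction * len(em.events))
        for idx in sorted(rng.sample(range(len(em.events)), n_corrupt)):
            kind = _corrupt(em.events[idx], rng)
            manifest["corrupted"].append(
                {"event_id": em.events[idx].event_id, "kind": kind}
            )
    return StreamBundle(events=em.events, manifest=manifest)


_REQUIRED_USED = {
    "specifying_simulation_experiment": "SimulationModel",
    "executing_simulation_experiment": "SimulationExperiment",
    "analyzing_simulation_data": "SimulationData",
}


def _corrupt(event: Event, rng: random.Random) -> str:
    """Corrupt one event in place; returns the corruption kind.

    Only violation classes the pattern engine detects are used, and the
    corruption never changes which entities downstream events can resolve
    (rejected generators simply bootstrap later as version 1), so the
    validity of every uncorrupted event is unaffected.
    """
    choices = ["missing-attribute", "unknown-activity"]
    required = _REQUIRED_USED.get(event.event_type)
    if required and any(d.entity_type == required for d in event.used):
        choices.append("missing-entity")
    kind = rng.choice(choices)
    if kind == "missing-entity":
        event.used = [d for d in event.used if d.entity_type != required]
    elif kind == "missing-attribute":
        # descriptors are shared across events; replace, never mutate in place
        blanked = dataclasses.replace(event.generated[0], name="")
        event.generated = [blanked] + event.generated[1:]
    else:
        event.event_type = "transmogrifying_" + event.event_type
    return kind


def fig2_stream() -> list:
    """The worked-example stream: two experiment executions on two models
    plus one analysis that visualizes both outputs.

    Ingesting it yields 8 entity versions (SM1, SM2, E1, E2, SD1, SD2, S,
    V), 3 activities, 2 agents (TEL, PY) and 13 dependency edges
    (7 used, 3 generated-by, 3 associated-with).
    """
    tel = AgentDescriptor(name="TEL", version="2.2")
    py = AgentDescriptor(name="PY", version="3.11")
    sm1 = _desc(EntityType.SIMULATION_MODEL, "SM1", "models/sm1.te")
    sm2 = _desc(EntityType.SIMULATION_MODEL, "SM2", "models/sm2.te")
    e1 = _desc(EntityType.SIMULATION_EXPERIMENT, "E1", "experiments/e1.py")
    e2 = _desc(EntityType.SIMULATION_EXPERIMENT, "E2", "experiments/e2.py")
    sd1 = _desc(EntityType.SIMULATION_DATA, "SD1", "data/sd1.csv", "t,x\n0,1\n")
    sd2 = _desc(EntityType.SIMULATION_DATA, "SD2", "data/sd2.csv", "t,x\n0,2\n")
    script = _desc(EntityType.SCRIPT, "S", "scripts/plot.py")
    vis = _desc(EntityType.VISUALIZATION, "V", "figs/v.svg", "<svg/>")
    return [
        Event(
            event_id="fig2-exec-1",
            event_type="executing_simulation_experiment",
            timestamp="2024-01-01T10:00:00Z",
            agent=tel,
            used=[sm1, e1],
            generated=[sd1],
        ),
        Event(
            event_id="fig2-exec-2",
            event_type="executing_simulation_experiment",
            timestamp="2024-01-01T10:05:00Z",
            agent=tel,
            used=[sm2, e2],
            generated=[sd2],
        ),
        Event(
            event_id="fig2-analyze",
            event_type="analyzing_simulation_data",
            timestamp="2024-01-01T10:10:00Z",
            agent=py,
            used=[sd1, sd2, script],
            generated=[vis],
        ),
    ]


def random_graph(seed: int, max_nodes: int = 25) -> ProvGraph:
    """A random valid provenance graph (typed, acyclic, versioned).

    Built directly through the graph primitives — activities use random
    subsets of existing versions (creating shortcut edges, which gives the
    transitive-reduction oracle something to remove) and either revise an
    existing identity or introduce a new one.
    """
    rng = random.Random(seed)
    graph = ProvGraph()
    agents = [graph.resolve_agent(f"tool-{i}", "1.0") for i in range(rng.randint(1, 2))]
    atypes = list(ActivityType)
    etypes = [
        EntityType.SIMULATION_MODEL,
        EntityType.SIMULATION_EXPERIMENT,
        EntityType.SIMULATION_DATA,
        EntityType.DATA,
        EntityType.SCRIPT,
    ]
    identities: list[EntityIdentity] = []
    n = 0
    while len(graph._g) < max_nodes - 3 and n < 40:
        n += 1
        act = ActivityNode(
            activity_type=rng.choice(atypes),
            timestamp=f"2024-02-0{rng.randint(1, 9)}T00:00:00Z",
            node_id=activity_node_id(f"rnd-{seed}-{n}"),
            source_event_id=f"rnd-{seed}-{n}",
        )
        graph.add_activity(act)
        existing = graph.entity_versions()
        for ev in rng.sample(existing, min(len(existing), rng.randint(0, 3))):
            latest = resolve_latest(graph, ev.identity)
            try:
                add_edge_checked(
                    graph,
                    DependencyEdge(EdgeKind.USED, act.node_id, latest.node_id),
                )
            except Exception:
                pass  # duplicate pick of one identity's latest
        n_gen = rng.randint(1, 2)
        for _ in range(n_gen):
            if identities and rng.random() < 0.4:
                identity = rng.choice(identities)
            else:
                etype = rng.choice(etypes)
                identity = EntityIdentity(
                    etype, f"files/f{len(identities)}.dat", f"f{len(identities)}"
                )
                identities.append(identity)
            version = graph.new_version(
                identity, {"name": identity.name, "path": identity.path}
            )
            add_edge_checked(
                graph,
                DependencyEdge(EdgeKind.GENERATED_BY, version.node_id, act.node_id),
            )
        add_edge_checked(
            graph,
            DependencyEdge(
                EdgeKind.ASSOCIATED_WITH, act.node_id, rng.choice(agents).node_id
            ),
        )
    return graph
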