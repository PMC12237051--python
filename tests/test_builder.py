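"""Event parsing, ingestion, chaining, error log, manual edits."""

import json

import pytest

import studyprov as sp
from studyprov import ActivityType, EdgeKind, EntityIdentity, EntityType
from studyprov.builder import (
    AgentDescriptor,
    DuplicateEventError,
    EntityDescriptor,
    InvalidAttributeError,
    MalformedEventError,
    MissingFieldError,
    parse_event,
)

MINIMAL_REFERENCE = json.dumps(
    {
        "event_id": "r1",
        "event_type": "specifying_reference",
        "agent": {"name": "editor"},
        "generated": [
            {"entity_type": "Reference", "name": "paper", "path": "refs/p.pdf"}
        ],
    }
)


def model_edit_event(eid, content="rule A\n"):
    return sp.Event(
        event_id=eid,
        event_type="specifying_simulation_model",
        agent=AgentDescriptor("editor", "1.0"),
        generated=[
            EntityDescriptor("SimulationModel", "m1", "m1.mlr", content=content)
        ],
    )


class TestParseEvent:
    def test_minimal_event(self):
        ev = parse_event(MINIMAL_REFERENCE)
        assert ev.event_type == "specifying_reference"
        assert len(ev.generated) == 1
        assert ev.generated[0].entity_type == "Reference"

    def test_executing_event_fully_populated(self):
        text = json.dumps(
            {
                "event_id": "x1",
                "event_type": "executing_simulation_experiment",
                "timestamp": "2024-01-01T00:00:00Z",
                "agent": {"name": "runner", "version": "2"},
                "used": [
                    {"entity_type": "SimulationModel", "name": "m", "path": "m.mlr"},
                    {"entity_type": "SimulationExperiment", "name": "e", "path": "e.py"},
                ],
                "generated": [
                    {
                        "entity_type": "SimulationData",
                        "name": "d",
                        "path": "d.csv",
                        "content_hash": "abc",
                    }
                ],
                "custom_key": {"nested": True},
            }
        )
        ev = parse_event(text)
        assert len(ev.used) == 2 and len(ev.generated) == 1
        assert ev.generated[0].content_hash == "abc"
        assert ev.extras == {"custom_key": {"nested": True}}  # unknown keys preserved

    def test_truncated_json(self):
        with pytest.raises(MalformedEventError):
            parse_event(MINIMAL_REFERENCE[:-10])

    @pytest.mark.parametrize("missing", ["event_id", "event_type", "generated"])
    def test_missing_required_field(self, missing):
        raw = json.loads(MINIMAL_REFERENCE)
        del raw[missing]
        with pytest.raises(MissingFieldError):
            parse_event(json.dumps(raw))


class TestIngest:
    def test_valid_event_extends_graph(self):
        state = sp.BuilderState()
        sp.ingest_event(state, model_edit_event("m-1"))
        ev = sp.Event(
            event_id="e-1",
            event_type="specifying_simulation_experiment",
            agent=AgentDescriptor("editor", "1.0"),
            used=[EntityDescriptor("SimulationModel", "m1", "m1.mlr")],
            generated=[EntityDescriptor("SimulationExperiment", "e1", "e1.py")],
        )
        sp.ingest_event(state, ev)
        stats = state.graph.stats()
        assert stats["activities"] == 2
        assert stats["entity_versions"] == 2
        assert not state.error_log

    def test_invalid_event_is_atomic_and_logged(self):
        state = sp.BuilderState()
        ev = sp.Event(
            event_id="bad-1",
            event_type="specifying_simulation_experiment",
            agent=AgentDescriptor("editor"),
            used=[],  # required model missing
            generated=[EntityDescriptor("SimulationExperiment", "e1", "e1.py")],
        )
        sp.ingest_event(state, ev)
        assert state.graph.stats()["activities"] == 0
        assert state.graph.stats()["entity_versions"] == 0
        assert len(state.error_log) == 1
        record = state.error_log[0]
        assert record.violations[0].code == "missing-entity"
        # the rejected event is stored verbatim
        assert json.loads(record.event_text)["event_id"] == "bad-1"

    def test_duplicate_event_id_rejected_without_change(self):
        state = sp.BuilderState()
        sp.ingest_event(state, model_edit_event("m-1"))
        before = state.graph.stats()
        with pytest.raises(DuplicateEventError):
            sp.ingest_event(state, model_edit_event("m-1", content="changed"))
        assert state.graph.stats() == before

    def test_stream_count_and_order(self):
        state = sp.BuilderState()
        events = [model_edit_event(f"m-{i}", content=f"rule {i}\n") for i in range(7)]
        for ev in events:
            sp.ingest_event(state, ev)
        assert len(state.graph.insertion_order) == 7
        got = [state.graph.node(a).source_event_id for a in state.graph.insertion_order]
        assert got == [ev.event_id for ev in events]

    def test_conservation_with_mixed_stream(self, ministudy):
        state, bundle = ministudy(seed=11, invalid_fraction=0.3)
        state2 = sp.BuilderState()
        for ev in bundle.events:
            sp.ingest_event(state2, ev)
        assert state2.check_conservation()


class TestChain:
    def test_two_edits_create_versions_with_revision(self):
        state = sp.BuilderState()
        sp.ingest_event(state, model_edit_event("m-1", "v1"))
        sp.ingest_event(state, model_edit_event("m-2", "v2"))
        identity = EntityIdentity(EntityType.SIMULATION_MODEL, "m1.mlr", "m1")
        versions = state.graph.versions_of(identity)
        assert [v.version for v in versions] == [1, 2]
        assert state.graph.has_edge(
            EdgeKind.REVISION_OF, versions[1].node_id, versions[0].node_id
        )
        # second activity's generation attaches to v2
        gen2 = state.graph.generated_entities(state.graph.insertion_order[1])
        assert gen2[0].version == 2

    def test_used_attaches_to_latest_version(self):
        state = sp.BuilderState()
        for i in range(3):
            sp.ingest_event(state, model_edit_event(f"m-{i}", f"v{i}"))
        exp = sp.Event(
            event_id="e-1",
            event_type="specifying_simulation_experiment",
            agent=AgentDescriptor("editor"),
            used=[EntityDescriptor("SimulationModel", "m1", "m1.mlr")],
            generated=[EntityDescriptor("SimulationExperiment", "e1", "e1.py")],
        )
        sp.ingest_event(state, exp)
        used = state.graph.used_entities(state.graph.insertion_order[-1])
        assert [u.version for u in used] == [3]

    def test_unseen_used_descriptor_bootstraps_version_1(self, fig2_state):
        # the script S was never generated by any activity, yet exists as v1
        identity = EntityIdentity(EntityType.SCRIPT, "scripts/plot.py", "S")
        versions = fig2_state.graph.versions_of(identity)
        assert [v.version for v in versions] == [1]

    def test_fig2_graph_shape(self, fig2_state):
        assert fig2_state.graph.stats() == {
            "entity_versions": 8,
            "activities": 3,
            "agents": 2,
            "edges": 13,
            "used": 7,
            "generated_by": 3,
            "associated_with": 3,
            "revision_of": 0,
        }

    def test_agents_are_deduplicated(self, fig2_state):
        names = sorted(a.name for a in fig2_state.graph.agents())
        assert names == ["PY", "TEL"]  # TEL appears once despite two events

    def test_replay_determinism_byte_identical_export(self):
        def build():
            state = sp.BuilderState()
            for ev in sp.fig2_stream():
                sp.ingest_event(state, ev)
            return sp.export_prov_json(state.graph)

        assert build() == build()

    def test_disjoint_events_commute_up_to_ids(self):
        a = model_edit_event("m-1")
        b = sp.Event(
            event_id="r-1",
            event_type="specifying_reference",
            agent=AgentDescriptor("editor"),
            generated=[EntityDescriptor("Reference", "p", "refs/p.pdf")],
        )
        s1, s2 = sp.BuilderState(), sp.BuilderState()
        sp.ingest_event(sp.ingest_event(s1, a), b)
        sp.ingest_event(sp.ingest_event(s2, b), a)
        assert sorted(n.node_id for n in s1.graph.nodes()) == sorted(
            n.node_id for n in s2.graph.nodes()
        )
        assert {(e.kind, e.source, e.target) for e in s1.graph.edges()} == {
            (e.kind, e.source, e.target) for e in s2.graph.edges()
        }

    def test_oversize_content_degrades_to_hash(self):
        state = sp.BuilderState(max_content_bytes=16)
        sp.ingest_event(state, model_edit_event("m-1", content="x" * 100))
        version = state.graph.entity_versions()[0]
        assert "content" not in version.attributes
        assert version.attributes["content_hash"]


class TestManualEdits:
    def _adapted_state(self):
        state = sp.BuilderState()
        bundle = sp.generate_stream(
            sp.StudyScript(phases=(sp.Phase("refine", 2), sp.Phase("adapt", 1)), seed=0)
        )
        for ev in bundle.events:
            sp.ingest_event(state, ev)
        return state

    def test_manual_dependency_links_adapted_model(self):
        """The clone relation between the adapted and the original model is
        invisible to capturers and must be addable by hand."""
        state = self._adapted_state()
        graph = state.graph
        adapt_act = next(
            a for a in graph.activities()
            if a.activity_type == ActivityType.SPECIFYING_SIMULATION_MODEL
            and graph.generated_entities(a.node_id)[0].identity.path.startswith("model_adapted")
        )
        original = sp.resolve_latest(
            graph, EntityIdentity(EntityType.SIMULATION_MODEL, "model_main.mlr", "")
        )
        sp.add_manual_dependency(state, adapt_act.node_id, original.node_id)
        edges = [e for e in graph.edges() if e.origin == "manual"]
        assert len(edges) == 1
        adapted = graph.generated_entities(adapt_act.node_id)[0]
        assert graph.reachable(adapted.node_id, original.node_id)

    def test_manual_cycle_rejected_state_unchanged(self):
        state = self._adapted_state()
        graph = state.graph
        first_act = graph.insertion_order[0]
        # an entity generated later in the study
        late_entity = graph.generated_entities(graph.insertion_order[-1])[0]
        before = len(graph.edges())
        with pytest.raises(sp.CycleError):
            sp.add_manual_dependency(state, first_act, late_entity.node_id)
        assert len(graph.edges()) == before

    def test_manual_duplicate_is_warned_noop(self):
        state = self._adapted_state()
        graph = state.graph
        act = graph.insertion_order[-1]
        target = graph.used_entities(act)[0]
        before = len(graph.edges())
        with pytest.warns(UserWarning, match="duplicates"):
            sp.add_manual_dependency(state, act, target.node_id)
        assert len(graph.edges()) == before


class TestFillAttribute:
    def test_fill_blank_specification(self, fig2_state):
        state = sp.BuilderState(graph=fig2_state.graph)
        version = state.graph.entity_versions()[0]
        sp.fill_attribute(state, version.node_id, "specification", "dose-response scan")
        assert version.attributes["specification"] == "dose-response scan"

    def test_fill_clears_revalidation_violation(self, fig2_state, patterns):
        state = sp.BuilderState(graph=fig2_state.graph, patterns=patterns)
        version = state.graph.entity_versions()[0]
        original = version.attributes["path"]
        version.attributes["path"] = ""
        assert sp.revalidate(state.graph, patterns)
        sp.fill_attribute(state, version.node_id, "path", original)
        assert sp.revalidate(state.graph, patterns) == []

    def test_required_attribute_must_stay_nonempty(self, fig2_state):
        state = sp.BuilderState(graph=fig2_state.graph)
        version = state.graph.entity_versions()[0]
        with pytest.raises(InvalidAttributeError):
            sp.fill_attribute(state, version.node_id, "name", "")

    def test_unknown_node(self, fig2_state):
        state = sp.BuilderState(graph=fig2_state.graph)
        with pytest.raises(sp.UnknownNodeError):
            sp.fill_attribute(state, "missing-node", "name", "x")


class TestJsonlIngestion:
    def test_malformed_lines_become_error_records(self, tmp_path):
        lines = [
            MINIMAL_REFERENCE,
            "{not json",
            json.dumps({"event_type": "specifying_reference", "generated": []}),
        ]
        state = sp.BuilderState()
        sp.ingest_jsonl(state, lines)
        assert len(state.graph.insertion_order) == 1
        assert len(state.error_log) == 2
        assert all(r.violations[0].code == "malformed-event" for r in state.error_log)
        assert state.check_conservation()
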