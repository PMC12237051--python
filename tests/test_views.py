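"""PROV-JSON round-trips, DOT export, and the two reduction views."""

import json

import networkx as nx
import pytest

import studyprov as sp
from studyprov import EdgeKind
from studyprov.views import (
    MalformedDocumentError,
    UnknownTypeError,
    aggregate_chains,
    export_dot,
    export_prov_json,
    import_prov_json,
    transitive_reduce,
)


def graph_signature(graph):
    """Ids + typed edges; equal signatures mean isomorphic-with-same-ids."""
    return (
        sorted(n.node_id for n in graph.nodes()),
        sorted((e.kind.value, e.source, e.target, e.origin) for e in graph.edges()),
        list(graph.insertion_order),
    )


def dependency_digraph(graph, with_revisions=True):
    g = nx.DiGraph()
    g.add_nodes_from(n.node_id for n in graph.nodes())
    for e in graph.edges():
        if with_revisions or e.kind != EdgeKind.REVISION_OF:
            g.add_edge(e.source, e.target)
    return g


class TestProvJson:
    def test_empty_graph_document(self):
        doc = json.loads(export_prov_json(sp.ProvGraph()))
        assert doc["prefix"]["simprov"]
        for section in ("entity", "activity", "agent", "used", "wasGeneratedBy",
                        "wasAssociatedWith"):
            assert doc[section] == {}

    def test_fig2_record_counts(self, fig2_state):
        doc = json.loads(export_prov_json(fig2_state.graph))
        assert len(doc["entity"]) == 8
        assert len(doc["activity"]) == 3
        assert len(doc["agent"]) == 2
        assert len(doc["used"]) == 7
        assert len(doc["wasGeneratedBy"]) == 3
        assert len(doc["wasAssociatedWith"]) == 3

    def test_fig2_round_trip_isomorphic(self, fig2_state):
        text = export_prov_json(fig2_state.graph)
        assert graph_signature(import_prov_json(text)) == graph_signature(fig2_state.graph)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graph_round_trip_reexport_byte_identical(self, seed):
        graph = sp.random_graph(seed)
        text = export_prov_json(graph)
        again = export_prov_json(import_prov_json(text))
        assert again == text

    def test_missing_namespace_is_malformed(self):
        doc = json.loads(export_prov_json(sp.ProvGraph()))
        del doc["prefix"]["simprov"]
        with pytest.raises(MalformedDocumentError):
            import_prov_json(json.dumps(doc))

    def test_not_json_is_malformed(self):
        with pytest.raises(MalformedDocumentError):
            import_prov_json("{")

    def test_foreign_entity_type_strict_vs_permissive(self, fig2_state):
        doc = json.loads(export_prov_json(fig2_state.graph))
        some_id = next(iter(doc["entity"]))
        doc["entity"][some_id]["prov:type"] = "ex:Widget"
        text = json.dumps(doc)
        with pytest.raises(UnknownTypeError):
            import_prov_json(text)
        with pytest.warns(UserWarning, match="foreign type"):
            graph = import_prov_json(text, strict=False)
        foreign = [
            ev for ev in graph.entity_versions()
            if not isinstance(ev.identity.entity_type, sp.EntityType)
        ]
        assert len(foreign) == 1

    def test_foreign_sections_preserved(self, fig2_state):
        doc = json.loads(export_prov_json(fig2_state.graph))
        doc["wasDerivedFrom"] = {"_:d1": {"prov:generatedEntity": "a", "prov:usedEntity": "b"}}
        graph = import_prov_json(json.dumps(doc))
        assert "wasDerivedFrom" in json.loads(export_prov_json(graph))

    def test_versions_survive_round_trip(self, ministudy):
        state, _ = ministudy(seed=2)
        graph = import_prov_json(export_prov_json(state.graph))
        identity = sp.EntityIdentity(sp.EntityType.SIMULATION_MODEL, "model_main.mlr", "")
        assert [v.version for v in graph.versions_of(identity)] == [1, 2, 3]


class TestAggregateChains:
    def _edit_chain_state(self, n=10):
        state = sp.BuilderState()
        from studyprov.builder import AgentDescriptor, EntityDescriptor

        for i in range(n):
            sp.ingest_event(
                state,
                sp.Event(
                    event_id=f"edit-{i}",
                    event_type="specifying_simulation_model",
                    agent=AgentDescriptor("editor", "1.0"),
                    generated=[
                        EntityDescriptor("SimulationModel", "m", "m.mlr", content=f"v{i}")
                    ],
                ),
            )
        return state

    def test_ten_consecutive_edits_collapse_to_one_aggregate(self):
        state = self._edit_chain_state(10)
        reduced = aggregate_chains(state.graph)
        activities = reduced.activities()
        assert len(activities) == 1
        assert activities[0].count == 10
        # the aggregate generates (exactly) the final version
        generated = reduced.generated_entities(activities[0].node_id)
        assert [g.version for g in generated] == [10]

    def test_phases_stay_distinct(self, ministudy):
        state, _ = ministudy(seed=0, refine=4)
        reduced = aggregate_chains(state.graph)
        per_type = {}
        for act in reduced.activities():
            per_type.setdefault(act.activity_type, []).append(act)
        # the four refine roles each collapse into one aggregate apiece
        assert len(per_type[sp.ActivityType.EXECUTING_SIMULATION_EXPERIMENT]) <= 2
        assert sum(a.count for acts in per_type.values() for a in acts) == len(
            state.graph.insertion_order
        )

    def test_no_chains_is_fixpoint(self, fig2_state):
        reduced = aggregate_chains(fig2_state.graph)
        assert graph_signature(reduced) == graph_signature(fig2_state.graph)

    def test_idempotence(self, ministudy):
        state, _ = ministudy(seed=1, refine=5)
        once = aggregate_chains(state.graph)
        twice = aggregate_chains(once)
        assert export_prov_json(twice) == export_prov_json(once)

    def test_reachability_not_lost_and_edges_justified(self, ministudy):
        """Quotient-closure check: every original reachability between
        surviving nodes survives, and every reduced edge is witnessed by a
        member-level original reachability."""
        state, _ = ministudy(seed=3, refine=4)
        graph = state.graph
        reduced = aggregate_chains(graph)
        mapping = {}
        for act in reduced.activities():
            for member in act.member_activity_ids or (act.node_id,):
                mapping[member] = act.node_id
        for node in graph.nodes():
            mapping.setdefault(node.node_id, node.node_id)
        surviving = {n.node_id for n in reduced.nodes()}
        orig = dependency_digraph(graph)
        red = dependency_digraph(reduced)
        orig_closure = nx.transitive_closure_dag(orig)
        red_closure = nx.transitive_closure_dag(red)
        # no loss
        for u, v in orig_closure.edges():
            mu, mv = mapping[u], mapping[v]
            if mu in surviving and mv in surviving and mu != mv:
                assert red_closure.has_edge(mu, mv), (u, v)
        # every reduced edge justified by some original member pair
        members = {}
        for orig_id, red_id in mapping.items():
            members.setdefault(red_id, set()).add(orig_id)
        for u, v in red.edges():
            assert any(
                orig_closure.has_edge(a, b) or a == b
                for a in members.get(u, {u})
                for b in members.get(v, {v})
            ), (u, v)

    def test_reduction_never_invents_nodes(self, ministudy):
        state, _ = ministudy(seed=4)
        original_ids = {n.node_id for n in state.graph.nodes()}
        reduced = aggregate_chains(state.graph)
        for act in reduced.activities():
            for member in act.member_activity_ids or (act.node_id,):
                assert member in original_ids
        for node in reduced.nodes():
            if not isinstance(node, sp.ActivityNode):
                assert node.node_id in original_ids


class TestTransitiveReduce:
    def test_shortcut_edge_removed(self):
        # chain a -> b -> c plus shortcut a -> c through manual usage
        state = sp.BuilderState()
        from studyprov.builder import AgentDescriptor, EntityDescriptor

        sp.ingest_event(
            state,
            sp.Event(
                event_id="x1",
                event_type="executing_simulation_experiment",
                agent=AgentDescriptor("runner"),
                used=[
                    EntityDescriptor("SimulationModel", "m", "m.mlr"),
                    EntityDescriptor("SimulationExperiment", "e", "e.py"),
                ],
                generated=[EntityDescriptor("SimulationData", "d", "d.csv")],
            ),
        )
        sp.ingest_event(
            state,
            sp.Event(
                event_id="a1",
                event_type="analyzing_simulation_data",
                agent=AgentDescriptor("py"),
                used=[EntityDescriptor("SimulationData", "d", "d.csv")],
                generated=[EntityDescriptor("Visualization", "v", "v.svg")],
            ),
        )
        graph = state.graph
        analyze = graph.insertion_order[1]
        model = sp.resolve_latest(
            graph, sp.EntityIdentity(sp.EntityType.SIMULATION_MODEL, "m.mlr", "")
        )
        sp.add_manual_dependency(state, analyze, model.node_id)  # redundant shortcut
        reduced = transitive_reduce(graph)
        assert not reduced.has_edge(EdgeKind.USED, analyze, model.node_id)
        # reachability is intact
        assert nx.has_path(dependency_digraph(reduced), analyze, model.node_id)

    def test_already_minimal_graph_unchanged(self, fig2_state):
        reduced = transitive_reduce(fig2_state.graph)
        assert graph_signature(reduced) == graph_signature(fig2_state.graph)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        graph = sp.random_graph(seed)
        reduced = transitive_reduce(graph)
        work = dependency_digraph(graph, with_revisions=False)
        # oracle: an edge is redundant iff a longer path also connects it
        expected = set()
        for u, v in work.edges():
            trimmed = work.copy()
            trimmed.remove_edge(u, v)
            if not nx.has_path(trimmed, u, v):
                expected.add((u, v))
        got = {
            (e.source, e.target) for e in reduced.edges() if e.kind != EdgeKind.REVISION_OF
        }
        assert got == expected
        # identical reachability matrices
        assert nx.transitive_closure_dag(work).edges() == nx.transitive_closure_dag(
            dependency_digraph(reduced, with_revisions=False)
        ).edges()

    def test_revision_edges_kept_verbatim(self, ministudy):
        state, _ = ministudy(seed=5)
        n_rev = state.graph.stats()["revision_of"]
        assert transitive_reduce(state.graph).stats()["revision_of"] == n_rev


class TestDot:
    def test_empty_graph_is_valid_digraph(self):
        text = export_dot(sp.ProvGraph())
        assert text.startswith("digraph") and text.rstrip().endswith("}")

    def test_fig2_statement_counts(self, fig2_state):
        text = export_dot(fig2_state.graph)
        node_lines = [l for l in text.splitlines() if "shape=" in l]
        edge_lines = [l for l in text.splitlines() if " -> " in l]
        assert len(node_lines) == 13
        assert len(edge_lines) == 13
        assert sum("shape=ellipse" in l for l in node_lines) == 8
        assert sum("shape=box" in l for l in node_lines) == 3
        assert sum("shape=house" in l for l in node_lines) == 2

    def test_manual_edge_styled(self, fig2_state):
        state = sp.BuilderState(graph=fig2_state.graph)
        act = state.graph.insertion_order[-1]
        target = next(
            ev for ev in state.graph.entity_versions()
            if ev.identity.entity_type == sp.EntityType.SIMULATION_MODEL
        )
        sp.add_manual_dependency(state, act, target.node_id)
        text = export_dot(state.graph)
        manual_lines = [l for l in text.splitlines() if "forestgreen" in l]
        assert len(manual_lines) == 1 and 'label="manual"' in manual_lines[0]

    def test_deterministic(self, ministudy):
        state, _ = ministudy(seed=6)
        assert export_dot(state.graph) == export_dot(state.graph)
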