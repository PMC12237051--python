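# studyprov

Provenance capture, validation, versioning, and chaining for simulation
studies.

Simulation studies in systems biology (and beyond) produce far more than a
final model: research questions, requirements, assumptions, qualitative
models, reference data, successive simulation-model versions, experiment
specifications, simulation data, analysis scripts and figures — all linked
by who used and produced what, with which tool. That web of dependencies
is usually reconstructed by hand after the fact, if at all. `studyprov`
records it while the study happens, as a single typed provenance graph,
for modelers who want their studies transparent, reproducible, and
reusable.

## The model

The graph is a PROV-DM extension. Nodes are **entities** (eleven study
product types, from `ResearchQuestion` to `Visualization`), **activities**
(eight modeler action types: specifying references / questions /
requirements / assumptions / models / experiments, executing experiments,
analyzing simulation data), and **agents** (the software systems
responsible for activities). Directed edges are

* *used* — activity → entity,
* *wasGeneratedBy* — entity → activity,
* *wasAssociatedWith* — activity → agent,
* *revisionOf* — entity version *k+1* → version *k*,

and the whole graph is acyclic. Entities are identified by
`(entity type, canonical file path)`; every edit creates a new immutable
version, and new dependencies always attach to the latest version.

Which combinations are valid per activity is specified declaratively as
YAML **provenance patterns** (required/optional entity types with
cardinalities, required attributes, agent rules). Capturers — a
file-tracking editor contract and an execution-wrapping helper — emit one
JSON **event** per activity; the **builder** validates each event against
its pattern and chains it into the graph, or discards it whole to an
inspectable error log. Two non-destructive views summarize the result:
*chain aggregation* (consecutive runs of the same activity type collapse
into one aggregate, exposing the phases of the study) and *transitive
reduction* (the unique minimal edge set with identical reachability).
Graphs serialize to PROV-JSON (round-trip, byte-stable) and Graphviz DOT.

## Worked example

Two simulation models are each run by their own experiment, and one Python
script visualizes both outputs:

```python
import studyprov as sp

state = sp.BuilderState()                 # default patterns
for event in sp.fig2_stream():            # 2 executions + 1 analysis
    sp.ingest_event(state, event)

print(state.graph.stats())
print(len(state.error_log), "rejected events")
```

prints

```
{'entity_versions': 8, 'activities': 3, 'agents': 2, 'edges': 13,
 'used': 7, 'generated_by': 3, 'associated_with': 3, 'revision_of': 0}
0 rejected events
```

— 8 entity versions (two models SM1/SM2, two experiments E1/E2, their
outputs SD1/SD2, the script S and the figure V), 3 activities, 2 agents
(the simulation tool TEL and the Python environment PY), and 13 typed
dependency edges. The used-descriptors for SM1, E1, S, … had never been
generated by any recorded activity, so the builder bootstrapped them as
version 1 — externally produced artifacts enter the graph the first time
something uses them.

The same pipeline from the shell:

```
studyprov fixtures --name ministudy --seed 5 --invalid-fraction 0.2 --out events.jsonl
studyprov ingest events.jsonl --out graph.provjson --state state.json
studyprov errors state.json
studyprov reduce --method chains --in graph.provjson --out phases.provjson
studyprov export graph.provjson --format dot
```

and `studyprov serve --port 8140` runs the REST builder
(`POST /events`, `GET /graph`, `GET /errors`, `GET /export?format=dot`).

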