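# Methods

## Provenance model

The graph follows W3C PROV-DM restricted and extended for simulation
studies. Three node kinds: *entity versions* (immutable snapshots of study
products), *activities* (modeler actions), *agents* (software systems;
treating software as agents rather than metadata emphasizes its
responsibility for results). Four edge kinds with fixed endpoint typing:
`USED` (activity→entity), `GENERATED_BY` (entity→activity),
`ASSOCIATED_WITH` (activity→agent), `REVISION_OF` (entity v(k+1)→v(k),
same identity). The full edge set must stay acyclic; `add_edge_checked`
verifies endpoint typing, duplicate-freedom and acyclicity before the
single mutation, so the graph is never half-modified.

Assumptions baked into the model:

* **Identity is lexical.** An evolving product is identified by
  `(entity type, canonical path)` — separators and redundant segments
  normalized, case preserved, never resolved against a filesystem. Two
  capturers reporting the same file therefore converge on one version
  chain; files renamed mid-study become new identities (a rename event is
  out of scope).
* **Versions are nodes.** Each edit creates the next version as a new
  node so that dependencies can address "the latest version at the time".
  Version numbers per identity are gapless 1..k, linked by a simple
  `REVISION_OF` path.
* **Arrival order is authoritative.** Events carry timestamps but
  ordering uses arrival order only; out-of-order timestamps are accepted
  with a logged warning. This keeps replays deterministic and sidesteps
  clock skew between capturers.
* **Deterministic ids.** Node ids are short hashes of stable keys
  (event id for activities, identity+version for entities, name+version
  for agents). Rebuilding from the same stream reproduces identical ids
  and byte-identical exports — replay equality is testable by `diff`.

## Patterns

A pattern constrains one activity type: per entity type and role
(used/generated) a count interval `[min, max]` (`min >= 1` = "always
uses/produces", `min = 0` = optional, `max` default unbounded), required
attributes per participant (default `name`, `path`; entities tolerate a
blank `specification`), and an agent requirement (default: required, with
`name`). Entity types outside the pattern's constraint list are
violations in strict mode — silently dropping them would hide capturer
bugs — and warnings in permissive mode. Matching is a pure function
returning all violations at once (codes: `missing-entity`,
`excess-entity`, `unknown-entity`, `missing-attribute`, `missing-agent`,
`unknown-activity`).

Only the experiment-specification pattern is fully fixed by the
provenance model (requires a simulation model; optionally an existing
experiment, an assumption, a requirement; produces one experiment). The
other seven shipped patterns are reconstructions from the study life
cycle, marked as such in `default_patterns.yaml`; notable choices:

* `ExecutingSimulationExperiment` requires *both* the experiment and the
  model (executions are observed using both), producing simulation data.
* `AnalyzingSimulationData` requires ≥1 simulation data, optionally a
  script, and produces a visualization (optionally derived data). The
  constraint language has no disjunction, so "visualization or data" is
  encoded as visualization-required — matching the worked example, where
  the analysis produces exactly the figure. Analyses that only transform
  data need a user pattern with `Data` required instead.
* `max = 1` is set only for the primary generated product of specifying
  activities; used-cardinalities stay unbounded because model comparison
  legitimately uses several models/data sets at once.
* There is no specifying activity for `QualitativeModel`, `Data` and
  `Script` (the activity taxonomy has eight members); these products
  enter the graph the first time an activity uses them.

## Builder

`ingest_event` is atomic and idempotent: a valid event contributes its
activity, versions and edges; an invalid one contributes exactly one
error-log record holding the event verbatim plus all violations; a
replayed `event_id` raises and changes nothing (at-least-once delivery is
safe). Conservation — accepted activities + error records = processed
events — is a state invariant. Used descriptors resolve to the latest
version or bootstrap version 1 (rejecting unknown used files would make
the pre-existing conceptual-model files impossible to reference).
Generated content is stored as an attribute up to a size cap (default
1 MiB), above which only the SHA-256 is kept. Manual completion is
limited to what an automatic capturer cannot know: `add_manual_dependency`
adds `USED` edges flagged `origin="manual"` (duplicates are warned no-ops,
cycle-closing edges rejected), and `fill_attribute` patches missing
attribute values (required ones must stay non-empty).

The REST front (`POST /events`, `GET /graph|/errors|/export`) runs on the
standard library's threading HTTP server behind one lock, which fixes the
ingestion order under concurrent capturers. Offline streams are JSONL,
one event per line; malformed lines become error records with positional
surrogate ids so conservation still holds.

## Views

**PROV-JSON.** Standard sections plus a `simprov:` namespace for the
domain types, version numbers, insertion order and the revision relation.
Export sorts keys and derives relation ids from endpoint hashes, so
export∘import∘export is byte-identical. Import is strict by default
(foreign entity types error); permissive mode imports them untyped with a
warning; foreign top-level sections survive round-trips untouched.

**Chain aggregation.** Two same-type activities belong to one chain when
one's generated version is used by the other, or the other's generated
version is its direct revision — connectivity through entity versions
only, so interleaved activities of other types (e.g. the executions
between successive model edits) do not break the chain. Chains collapse
into one aggregate activity carrying `member_activity_ids` and `count`.
Entity versions generated *and* superseded strictly inside one aggregate,
and never used outside it, are elided; everything else survives, so a
10-edit chain renders as one aggregate generating the final version.
Merging nodes necessarily coarsens reachability: the aggregate inherits
the union of its members' external dependencies, so a node reaching one
member reaches everything any member used. The guaranteed (and tested)
properties are therefore: no reachability between surviving nodes is
lost, every reduced edge is witnessed by some member-level reachability,
acyclicity is preserved (in pathological mutual-dependency interleavings
the offending inherited usage edges are dropped), and the view is
idempotent and non-destructive. Exact closure equality is not claimed —
it is unattainable for any activity-merging view.

**Transitive reduction.** Computed on the typed edge set minus
`REVISION_OF` (version chains are semantic history, not redundancy, and
are kept verbatim) via the unique DAG transitive reduction; the test
suite checks it against a brute-force per-edge redundancy oracle and
compares reachability matrices.

**DOT.** Entities/activities/agents as ellipse/box/house, deterministic
statement order, manual edges green and labelled, aggregates annotated
with their member count.

## Synthetic streams

`generate_stream` scripts a miniature study in three phase kinds:
*conceptual* (reference, question, assumption, requirement — 4 events per
iteration), *refine* (model edit, experiment edit, execution, analysis —
4 events per iteration, all four files revised in place so consecutive
iterations form chains), *adapt* (model clone under a new path, execution,
comparative analysis — 3 events; the clone's origin is deliberately not
captured, providing the canonical manual-dependency case). Defaults used
throughout the tests: one conceptual iteration, three refine iterations,
one adapt iteration, corruption fraction 0.2 where corruption is tested;
reduction oracles use 200 random DAGs of ≤ 25 nodes and round-trips use
100 graphs — sizes at which the brute-force oracles are exact and fast.
Streams are byte-deterministic in `(script, seed)`. Corruptions draw only
from violation classes the pattern engine detects (required entity
removed, required attribute blanked, activity type unknown), are listed
in a sidecar manifest, and never change the validity of uncorrupted
events (a rejected generator's file simply bootstraps later as
version 1) — so the expected error log is exactly the manifest.

What the generator does *not* emulate: real tool heterogeneity (agents
are three fixed tool descriptors), wall-clock timing, concurrent
capturers, renames/deletions, or meaningful file contents (tiny
deterministic text blobs stand in for model code). Passing tests
therefore demonstrate the bookkeeping — validation, chaining, versioning,
reduction, serialization — not robustness to messy real-world capture.

## Numerical / degenerate-input choices

* Empty streams yield empty (but exportable) graphs; every section is
  present in PROV-JSON even when empty.
* Duplicate used-descriptors within one event collapse to one edge.
* An event whose generated path equals a used path revises the used
  identity (self-edit): the activity uses v(k) and generates v(k+1).
* Tie-breaks are lexical everywhere (sorted keys, sorted DOT statements);
  no randomness exists outside the synthetic generators, which take
  explicit seeds.

## Known limitations

* Patterns are local to one activity; cross-activity rules ("validate
  before predict") are out of scope.
* No persistence beyond PROV-JSON/state files; no authentication or
  multi-user sessions on the REST service.
* Chain aggregation approximates phase detection by same-type
  connectivity; it does not merge repeated entities across iterations in
  the underlying data (they are only elided from the view when purely
  internal).
* Renaming a file starts a new identity; linking it to its predecessor
  requires a manual dependency.
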