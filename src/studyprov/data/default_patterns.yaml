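# Default provenance patterns for the eight simulation-study activity types.
#
# Only SpecifyingSimulationExperiment is fully fixed by the provenance model
# (always uses a simulation model; optionally an existing experiment, an
# assumption and/or a requirement; always produces a simulation experiment;
# name and file path are required attributes, the specification may be
# blank). The remaining seven are reconstructed from the study life cycle
# the model encodes and are marked "reconstructed".
#
# Defaults applied by the loader: min 0, max unbounded,
# required_attributes [name, path] for entities, [name] for agents.

patterns:
  # reconstructed: a reference is recorded from outside the study
  - activity: SpecifyingReference
    uses: []
    generates:
      - {entity: Reference, min: 1, max: 1}
    agent: {required: true, required_attributes: [name]}

  # reconstructed: questions may cite references
  - activity: SpecifyingResearchQuestion
    uses:
      - {entity: Reference}
    generates:
      - {entity: ResearchQuestion, min: 1, max: 1}
    agent: {required: true, required_attributes: [name]}

  # reconstructed: requirements substantiate the question, may cite references
  - activity: SpecifyingRequirement
    uses:
      - {entity: Reference}
      - {entity: ResearchQuestion}
    generates:
      - {entity: Requirement, min: 1, max: 1}
    agent: {required: true, required_attributes: [name]}

  # reconstructed: assumptions are deduced from references / the question
  - activity: SpecifyingAssumption
    uses:
      - {entity: Reference}
      - {entity: ResearchQuestion}
    generates:
      - {entity: Assumption, min: 1, max: 1}
    agent: {required: true, required_attributes: [name]}

  # reconstructed: a model draws on the whole conceptual model and possibly
  # on other models (re-implementation, adaptation)
  - activity: SpecifyingSimulationModel
    uses:
      - {entity: Assumption}
      - {entity: Requirement}
      - {entity: QualitativeModel}
      - {entity: Data}
      - {entity: Reference}
      - {entity: ResearchQuestion}
      - {entity: SimulationModel}
    generates:
      - entity: SimulationModel
        min: 1
        max: 1
        required_attributes: [name, path]
        optional_attributes: [specification, content, content_hash]
    agent: {required: true, required_attributes: [name]}

  # fixed by the provenance model (see header)
  - activity: SpecifyingSimulationExperiment
    uses:
      - {entity: SimulationModel, min: 1}
      - {entity: SimulationExperiment}
      - entity: Assumption
        required_attributes: [name, path]
        optional_attributes: [specification]
      - entity: Requirement
        required_attributes: [name, path]
        optional_attributes: [specification]
    generates:
      - entity: SimulationExperiment
        min: 1
        max: 1
        required_attributes: [name, path]
        optional_attributes: [specification, content, content_hash]
    agent: {required: true, required_attributes: [name]}

  # reconstructed: an execution uses the experiment and the model it runs
  # and produces the simulation data
  - activity: ExecutingSimulationExperiment
    uses:
      - {entity: SimulationExperiment, min: 1}
      - {entity: SimulationModel, min: 1}
    generates:
      - {entity: SimulationData, min: 1}
    agent: {required: true, required_attributes: [name]}

  # reconstructed: analysis consumes simulation data, optionally through a
  # script, and yields visualizations (and possibly derived data)
  - activity: AnalyzingSimulationData
    uses:
      - {entity: SimulationData, min: 1}
      - {entity: Script}
    generates:
      - {entity: Visualization, min: 1}
      - {entity: Data}
    agent: {required: true, required_attributes: [name]}
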