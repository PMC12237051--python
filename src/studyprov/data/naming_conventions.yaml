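# File-name prefix conventions used to infer entity types during capture.
# Edit freely; unknown files fall back to explicit typing by the modeler.
prefixes:
  reference_: Reference
  question_: ResearchQuestion
  requirement_: Requirement
  assumption_: Assumption
  qualitative_: QualitativeModel
  data_: Data
  model_: SimulationModel
  experiment_: SimulationExperiment
  script_: Script
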