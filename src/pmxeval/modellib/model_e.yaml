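label: model_e
description: >
  Representative parent-only model: 2-compartment parent with first-order
  absorption and lag time, two-subpopulation mixture on clearance (poor /
  normal metabolizers), allometric weight scaling, residual error additive
  on the log scale (the model was developed on log-transformed
  concentrations).  Parameter values are synthetic/representative
  placeholders for testing, not published estimates.
analytes:
  - {name: risperidone, molecular_weight: 410.485, role: parent}
structure: {parent_compartments: 2, has_metabolite: false, lag: true}
theta:
  cl: 24.0
  v: 260.0
  q: 25.0
  vp: 440.0
  ka: 1.4
  alag: 0.25
  f: 1.0
mixture:
  labels: [poor, normal]
  proportions: [0.13, 0.87]
  overrides:
    poor: {cl: 4.5}
    normal: {cl: 24.0}
random_effects:
  names: [cl, v]
  omega:
    - [0.40]
    - [0.00, 0.30]
covariates: allometric
error:
  risperidone: {additive: 0.45, scale: log}
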