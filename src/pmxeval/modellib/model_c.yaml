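label: model_c
description: >
  Representative adult joint parent-metabolite model: 1-compartment parent
  and metabolite with first-order absorption, three-subpopulation mixture
  on parent clearance and fraction metabolized, no covariates (evaluated
  as reported for adults).  Parameter values are synthetic/representative
  placeholders for testing, not published estimates.
analytes:
  - {name: risperidone, molecular_weight: 410.485, role: parent}
  - {name: 9-OH-risperidone, molecular_weight: 425.91, role: metabolite}
structure: {parent_compartments: 1, has_metabolite: true, lag: false}
theta:
  cl: 26.0
  v: 280.0
  ka: 1.0
  fm: 0.13
  clm: 6.0
  vm: 200.0
  f: 1.0
mixture:
  labels: [poor, intermediate, normal]
  proportions: [0.10, 0.17, 0.73]
  overrides:
    poor: {cl: 4.0, fm: 0.16}
    intermediate: {cl: 11.0, fm: 1.0}
    normal: {cl: 26.0, fm: 0.13}
random_effects:
  names: [cl, v, clm]
  omega:
    - [0.35]
    - [0.00, 0.30]
    - [0.00, 0.00, 0.25]
covariates: []
error:
  risperidone: {additive: 2.4e-4, proportional: 0.30, scale: natural}
  9-OH-risperidone: {additive: 2.3e-4, proportional: 0.28, scale: natural}
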