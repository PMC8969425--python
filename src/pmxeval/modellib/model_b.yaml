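label: model_b
description: >
  Representative pediatric joint parent-metabolite model: 1-compartment
  parent and metabolite with first-order absorption, three-subpopulation
  mixture on parent clearance and fraction metabolized (poor /
  intermediate / normal metabolizers; the intermediate fraction
  metabolized fixed to 1), allometric weight scaling.  Parameter values
  are synthetic/representative placeholders for testing, not published
  estimates.
analytes:
  - {name: risperidone, molecular_weight: 410.485, role: parent}
  - {name: 9-OH-risperidone, molecular_weight: 425.91, role: metabolite}
structure: {parent_compartments: 1, has_metabolite: true, lag: false}
theta:
  cl: 20.0
  v: 150.0
  ka: 1.0
  fm: 0.13
  clm: 4.5
  vm: 140.0
  f: 1.0
mixture:
  labels: [poor, intermediate, normal]
  proportions: [0.12, 0.20, 0.68]
  overrides:
    poor: {cl: 3.0, fm: 0.16}
    intermediate: {cl: 9.0, fm: 1.0}
    normal: {cl: 20.0, fm: 0.13}
random_effects:
  names: [cl, v, clm]
  omega:
    - [0.40]
    - [0.00, 0.35]
    - [0.00, 0.00, 0.30]
covariates: allometric
error:
  risperidone: {additive: 2.4e-4, proportional: 0.30, scale: natural}
  9-OH-risperidone: {additive: 2.3e-4, proportional: 0.30, scale: natural}
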