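label: model_a
description: >
  Representative pediatric joint parent-metabolite model: 2-compartment
  parent with first-order absorption and lag time, 1-compartment
  metabolite, allometric weight scaling, no mixture.  Parameter values are
  synthetic/representative placeholders for testing, not published
  estimates.
analytes:
  - {name: risperidone, molecular_weight: 410.485, role: parent}
  - {name: 9-OH-risperidone, molecular_weight: 425.91, role: metabolite}
structure: {parent_compartments: 2, has_metabolite: true, lag: true}
theta:
  cl: 12.0      # L/h per 70 kg
  v: 110.0      # L per 70 kg
  q: 18.0
  vp: 350.0
  ka: 1.2       # 1/h
  alag: 0.35    # h
  fm: 0.70
  clm: 5.0
  vm: 120.0
  f: 1.0
random_effects:
  names: [cl, v, clm]
  omega:
    - [0.50]
    - [0.00, 0.30]
    - [0.00, 0.00, 0.25]
covariates: allometric
error:
  risperidone: {additive: 2.4e-4, proportional: 0.35, scale: natural}
  9-OH-risperidone: {additive: 2.3e-4, proportional: 0.30, scale: natural}
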