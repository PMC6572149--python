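# Reference study configuration: 200 coded gas-explosion accidents
# (2001-2015), factor elicitation ranges, per-cell hazard-index normals
# and simulation settings.
#
# Note: the gas_prevention_fire/UUD hazard sd of 0.0135 is the encoding
# consistent with the published risk moments for that cell; the source
# table's entry for it is corrupted.
study:
  n_accidents: 200
model:
  org_weights: [0.2, 0.6, 0.2]
  slope: 0.0167
  intercept: 1.5
simulation:
  iterations: 10000
  seed: 1
  confidence: 0.95
  truncation: none
  total_mode: comonotonic
working_types:
  ventilation:
    name: Ventilation
    is_key: true
    factors:
      a: [0, 1]
      b: [0, 1]
      c: [3, 10]
      d: [3, 10]
      e: [0, 1]
      f: [3, 10]
      g: [1, 3]
      h: [0, 1]
    behaviors:
      OIW: {count: 32, hazard: {mean: 2.0, sd: 1.2}}
      FSD: {count: 19, hazard: {mean: 0.125, sd: 0.045}}
      UUD: {count: 15, hazard: {mean: 1.5, sd: 0.6}}
      VDP: {count: 6, hazard: {mean: 0.45, sd: 0.15}}
      RIW: {count: 10, hazard: {mean: 0.25, sd: 0.19}}
  gas_prevention_fire:
    name: Gas prevention and fire extinguishing
    is_key: true
    factors:
      a: [0, 1]
      b: [0, 1]
      c: [1, 3]
      d: [3, 10]
      e: [0, 1]
      f: [3, 10]
      g: [1, 3]
      h: [0, 1]
    behaviors:
      OIW: {count: 21, hazard: {mean: 2.25, sd: 1.05}}
      FSD: {count: 8, hazard: {mean: 0.1, sd: 0.085}}
      UUD: {count: 17, hazard: {mean: 0.2, sd: 0.0135}}
      VDP: {count: 3, hazard: {mean: 0.1, sd: 0.07}}
      WHD: {count: 2, hazard: {mean: 0.125, sd: 0.09}}
      MFE: {count: 8, hazard: {mean: 0.125, sd: 0.1}}
  blasting:
    name: Blasting
    is_key: true
    factors:
      a: [0, 1]
      b: [0, 1]
      c: [1, 3]
      d: [1, 3]
      e: [0, 1]
      f: [3, 10]
      g: [3, 10]
      h: [0, 1]
    behaviors:
      OIW: {count: 9, hazard: {mean: 2.5, sd: 1.6}}
      FSD: {count: 4, hazard: {mean: 0.5, sd: 0.145}}
      UUD: {count: 13, hazard: {mean: 2.5, sd: 0.75}}
      VDP: {count: 2, hazard: {mean: 2.0, sd: 1.4}}
      RIW: {count: 2, hazard: {mean: 0.25, sd: 0.14}}
      MFE: {count: 7, hazard: {mean: 2.5, sd: 1.8}}
  electrician:
    name: Electrician
    is_key: true
    factors:
      a: [0, 1]
      b: [0, 1]
      c: [3, 10]
      d: [3, 10]
      e: [0, 1]
      f: [3, 10]
      g: [1, 3]
      h: [0, 1]
    behaviors:
      OIW: {count: 7, hazard: {mean: 2.0, sd: 0.45}}
      FSD: {count: 2, hazard: {mean: 0.3, sd: 0.125}}
      UUD: {count: 3, hazard: {mean: 2.5, sd: 1.25}}
      VDP: {count: 5, hazard: {mean: 0.3, sd: 0.15}}
      RIW: {count: 2, hazard: {mean: 0.225, sd: 0.11}}
      PPE: {count: 3, hazard: {mean: 0.4, sd: 0.16}}
  mining:
    name: Mining
    is_key: false
  transport:
    name: Transport
    is_key: false
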