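# Example condition/scan configuration for the bundled mini-plant
# (apply with e.g. `rhizoflux fba --in ... --config fixtures/conditions.yaml
#  --condition night_on_ammonium`).
conditions:
  night_on_ammonium:
    bounds:
      EX_photon: [0, 0]
      EX_starch: [-1000, 0]
      EX_mal: [0, 0]
      EX_succ: [0, 0]
      EX_nh4: [-1000, 0]
      EX_no3: [0, 0]
  day_on_nitrate:
    bounds:
      EX_photon: [-100, 0]
      EX_starch: [0, 1000]
      EX_nh4: [0, 0]
      EX_no3: [-1000, 0]
scans:
  nitrogen_mixture:
    kind: nitrogen
    points: 21
    growth: 0.1
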