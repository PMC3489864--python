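units:
  rates: 1/h
  delays: h
variables:
- Bmal1
- Rev-erba
- Per2
- Cry1
- Rorg
- Dbp
degradation_rates:
  Bmal1: 0.33255801330303364
  Rev-erba: 0.483481386004701
  Per2: 0.27744355923141073
  Cry1: 0.15522991021538024
  Rorg: 0.12608150884044203
  Dbp: 0.5188147978339342
production_scale:
  Bmal1: 14.089120953985066
  Rev-erba: 0.05156409340888414
  Per2: 1.3163075420262635
  Cry1: 1.0
  Rorg: 1.0
  Dbp: 11.889029708921724
productions:
  Bmal1:
  - regulator: Rev-erba
    role: inhibitor
    delay_h: 1.5785991125613892
    exponent: 2
    basal: 1.0
    saturation: 0.8560681995297326
    strength: 1.0
    kd: 1.0
  Rev-erba:
  - regulator: Bmal1
    role: activator
    delay_h: 4.0
    exponent: 3
    basal: 1.0
    saturation: 20.057251748247364
    strength: 57.509933020813826
    kd: 1.0
  - regulator: Per2
    role: inhibitor
    delay_h: 8.4
    exponent: 3
    basal: 1.0
    saturation: 7.319775964039101
    strength: 1.0
    kd: 1.0
  Per2:
  - regulator: Bmal1
    role: activator
    delay_h: 4.0
    exponent: 2
    basal: 1.0
    saturation: 20.057251748247364
    strength: 1.7899425221808514
    kd: 1.0
  - regulator: Per2
    role: inhibitor
    delay_h: 8.4
    exponent: 2
    basal: 1.0
    saturation: 0.15625631781485533
    strength: 1.0
    kd: 1.0
  - regulator: Dbp
    role: activator
    delay_h: 0.8132693824929057
    exponent: 1
    basal: 1.0
    saturation: 0.6283445375152966
    strength: 59.68822645354461
    kd: 1.0
  Cry1:
  - regulator: Bmal1
    role: activator
    delay_h: 4.0
    exponent: 1
    basal: 1.0
    saturation: 2.8021651876015903
    strength: 2.048187562119729
    kd: 1.0
  - regulator: Per2
    role: inhibitor
    delay_h: 8.4
    exponent: 1
    basal: 1.0
    saturation: 0.1879470990897553
    strength: 1.0
    kd: 1.0
  - regulator: Dbp
    role: activator
    delay_h: 0.8132693824929057
    exponent: 1
    basal: 1.0
    saturation: 2.1354114924516048
    strength: 8.677140822300116
    kd: 1.0
  - regulator: Rev-erba
    role: inhibitor
    delay_h: 1.5785991125613892
    exponent: 2
    basal: 1.0
    saturation: 0.3459055313995899
    strength: 1.0
    kd: 1.0
  Rorg:
  - regulator: Bmal1
    role: activator
    delay_h: 4.0
    exponent: 2
    basal: 1.0
    saturation: 0.44660525825173997
    strength: 12.237821721030306
    kd: 1.0
  - regulator: Per2
    role: inhibitor
    delay_h: 8.4
    exponent: 2
    basal: 1.0
    saturation: 4.124460400123205
    strength: 1.0
    kd: 1.0
  - regulator: Dbp
    role: activator
    delay_h: 0.8132693824929057
    exponent: 1
    basal: 1.0
    saturation: 0.8765916797318173
    strength: 5.10184385700907
    kd: 1.0
  - regulator: Rev-erba
    role: inhibitor
    delay_h: 1.5785991125613892
    exponent: 1
    basal: 1.0
    saturation: 0.4282687865029754
    strength: 1.0
    kd: 1.0
  Dbp:
  - regulator: Bmal1
    role: activator
    delay_h: 4.0
    exponent: 3
    basal: 1.0
    saturation: 20.057251748247364
    strength: 13.831676433409633
    kd: 1.0
  - regulator: Per2
    role: inhibitor
    delay_h: 8.4
    exponent: 3
    basal: 1.0
    saturation: 2.49575613698723
    strength: 1.0
    kd: 1.0
forcing: null
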