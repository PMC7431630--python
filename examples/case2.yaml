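# Loading case 2 with the default geometry and controller gains.
geometry:
  nodes_mm: [[38, 0.4], [80, 1.7], [105, 3.0], [150, 6.2], [190, 10.0]]
  EI: 1.9
  area_mm2: 1225
muscles:
  f_max: 800
  passive: slack
controller:
  h1: 2.0
  h2: 2.0
  h3: 2.0
  k_alpha: 0.2
  k_e: {L1: 15, L2: 7, L3: 2.5, L4: 1, L5: 0.1}
  eta: 0.3
  grid: 7
  windup: 50
simulation:
  dt: 0.001
  t_end: 25
  nodal_mass: 0.1
  rayleigh_beta: 1.0
loads:
  P: [350, 50, 50, 50, 50]
  D_mm: 50
  ramp_time: 0.2
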