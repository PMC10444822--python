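# Intermediate jaw (2P3MR): two premolars and three molars.  The premolar
# region grows too little for a third insertion (dP3's successor is lost),
# while the molar region still accommodates all three molars.
name: intermediate_jaw
t_end: 150.0
record_every: 0.5
premolar:
  D_u: 1.0
  D_v: 40.0
  kinetics: {name: schnakenberg, a: 0.1, b: 0.9, gamma: 1.0}
  grid: {dx: 0.25, dt: 0.05, L0: 12.0}
  growth:
    mode: apical
    direction: anterior
    stage0: 19
    time_per_stage: 25.0
    schedule: [[19, 3.0], [20, 6.0], [21, 4.0], [22, 2.0], [23, 0.0]]
  gradient: {shape: none}
  detection: {threshold_frac: 0.5, floor_frac: 0.2, confirm_frames: 3, size_delay: 12.0}
  seed: 31
molar:
  D_u: 1.0
  D_v: 40.0
  kinetics: {name: schnakenberg, a: 0.1, b: 0.9, gamma: 1.0}
  grid: {dx: 0.25, dt: 0.05, L0: 12.0}
  growth:
    mode: apical
    direction: posterior
    stage0: 19
    time_per_stage: 25.0
    schedule: [[19, 10.0], [20, 14.0], [21, 10.0], [22, 0.0]]
  gradient: {shape: none}
  detection: {threshold_frac: 0.5, floor_frac: 0.2, confirm_frames: 3, size_delay: 12.0}
  seed: 32
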