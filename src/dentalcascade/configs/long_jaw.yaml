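# Long jaw (3P3ML): nectarivore phenotype, three premolars and three molars
# with a sharp early growth burst in the premolar region.  The burst opens
# space for dP3 and P2 almost simultaneously: the interval between the 2nd
# and 3rd premolar insertions is a fraction of the regular-jaw interval.
name: long_jaw
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
    schedule: [[19, 1.0], [19.4, 70.0], [19.8, 1.0], [21, 0.0]]
  gradient: {shape: none}
  detection: {threshold_frac: 0.5, floor_frac: 0.2, confirm_frames: 3, size_delay: 12.0}
  seed: 21
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
    schedule: [[19, 12.0], [20, 12.0], [21, 12.0], [22, 0.0]]
  gradient: {shape: none}
  detection: {threshold_frac: 0.5, floor_frac: 0.2, confirm_frames: 3, size_delay: 12.0}
  seed: 22
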