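# Short jaw (Artibeus-like, 2P3MS): two premolars; three molars of
# monotonically decreasing size.  The premolar region grows slowly and flat
# (no growth peak), yielding only two insertions.  The molar cascade runs
# under an exogenous exponential gradient that depresses the substrate
# production constant b toward the posterior: later molar peaks are smaller,
# and lowering the gradient floor to ~0.3 suppresses the M3 entirely
# (the polymorphic M3-loss phenotype).
name: short_jaw_artibeus
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
    schedule: [[19, 3.5], [20, 3.5], [21, 3.5], [22, 3.5], [23, 0.0]]
  gradient: {shape: none}
  detection: {threshold_frac: 0.5, floor_frac: 0.2, confirm_frames: 3, size_delay: 12.0}
  seed: 41
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
  gradient: {shape: exponential, target: b, floor: 0.4, scale: 30.0}
  detection: {threshold_frac: 0.5, floor_frac: 0.2, confirm_frames: 3, size_delay: 12.0}
  seed: 42
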