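# Example configuration for the `morph` CLI.
#
#   morph shape --config examples/run_config.yaml --out out/shape
#   morph tbm   --config examples/run_config.yaml --out out/tbm
#   morph stereo --config examples/run_config.yaml --out out/stereo
#
# Desk-scale cohort: three groups of 4 (raise n_per_group to 8 for the full
# study design), one planted outward deformation in the HAL group.

mode: shape
seed: 42
n_per_group: 4
groups: [VEH, HAL, OLZ]
subject_noise: 0.1          # mm RMS of the smooth per-subject surface noise

grid:
  shape: [96, 96, 40]
  spacing: [0.25, 0.25, 0.5]   # mm; slice axis last

effects:
  - center: [11.0, 15.0, 10.0]  # world mm, on the template surface
    radius: 2.5                 # support radius (mm)
    amplitude: 0.4              # signed; positive = outward
    group: HAL

mesh_vertices: 1300

registration:
  n_iterations: 60
  beta_start: 10.0
  beta_end: 0.1
  angle_tolerance_deg: 60.0

stats:
  q: 0.05
  n_permutations: 5000
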