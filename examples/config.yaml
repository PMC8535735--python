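# Full default study configuration (all values shown are the defaults;
# an empty file gives the same run).
geometry:
  length: 70.0            # mm, X (anteroposterior)
  width: 60.0             # mm, Y
  height: 40.0            # mm, bounding height of the bowl
  sheet_thickness: 6.0    # mm
  hiatus_semiaxes: [25.0, 15.0]   # mm, elliptical urogenital hiatus
  bowl_profile: 1.0
  plateau_fraction: 0.55
  rng_seed: 0

material:
  young_modulus: 0.2      # MPa
  poisson_ratio: 0.4
  density: 1.12e-9        # ton/mm^3

sphere:
  diameters: [80, 90, 100]  # mm, biparietal diameters to sweep
  density: 7.86e-9          # ton/mm^3 (3.0 kg at 90 mm)

contact:
  friction_coefficient: 0.03
  penalty_stiffness: null   # auto-scaled for <= 0.1 mm penetration
  friction_regularization_velocity: 1.0   # mm/s
  penetration_tolerance: 0.1              # mm

simulation:
  duration: 0.15            # s
  snapshot_interval: 0.03   # s -> 6 snapshots
  gravity: 9810.0           # mm/s^2, -Z
  cfl_factor: 0.8
  damping_ratio: 0.05
  initial_gap: 23.0         # mm
  mesh_edge: 3.0            # mm (2.0 reproduces the source protocol)
  monitor_every: 100
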