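# Packaged defaults for the spectsuv pipeline.  Any user config overlays
# these section by section; CLI flags override both.

quantification:
  half_life_h: 6.0067      # Tc-99m physical half-life, hours
  decay_numerator: 0.693   # rounded ln 2 of the clinical formula sheet

segmentation:
  frac: 0.40               # VOI threshold as a fraction of the seed SUV
  radius_mm: 15.0          # VOI / exclusion ball radius, mm
  k_max: 5                 # lesions extracted per volume per category
  floor: null              # stop floor, g/mL; null = 2 x median nonzero
  match_radius_mm: 20.0    # VOI-to-label seed matching distance, mm

stats:
  bin_edges: [20.0, 27.0]  # SUVmax breakdown edges, g/mL
  ci_level: 0.95

cohort:
  n_patients: 70
  n_metastatic: 236
  n_degenerative: 179
  max_lesions_per_category: 5
  age_mean_sd: [59.36, 11.45]          # years
  activity_mean_sd: [673.61, 56.64]    # MBq injected
  delay_mean_sd: [176.32, 34.47]       # minutes injection -> scan
  weight_mean_sd: [70.0, 12.0]         # kg
  weight_bounds: [40.0, 120.0]
  height_mean_sd: [163.0, 7.0]         # cm
  height_bounds: [140.0, 185.0]
  metastatic_targets: [32.56, 16.39, 10.90, 130.70]   # mean, sd, lo, hi
  degenerative_targets: [10.26, 4.67, 3.50, 27.00]
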