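# Crop parameter blocks.
#
# Feddes pressure heads [m] are the conventional crop-database DEFAULTS for
# potato and wheat-type cereals (they are defaults, not site calibrations;
# override per site as needed). Osmotic threshold/slope are the
# threshold-slope salinity-stress parameters used for these crops.
# Kc values and season dates correspond to the monitored seasons; stage
# fractions follow standard single-coefficient stage-length tables scaled
# to the season length.
potato:
  root_depth: 0.6
  feddes: {h1: -0.10, h2: -0.25, h3_high: -3.20, h3_low: -6.00, h4: -160.0}
  t_high: 5.0
  t_low: 1.0
  osmotic: {ec_threshold: 3.40, slope_pct: 6.0}
  kc: {ini: 0.5, mid: 1.15, end: 0.75}
  stage_fractions: [0.19, 0.23, 0.35, 0.23]
  # literature LAI trajectory: 1 -> 3.5 m2 m-2 over development, senescing back
  lai_points: [[0.0, 1.0], [0.42, 3.5], [0.77, 3.5], [1.0, 1.0]]

barley:
  root_depth: 1.0
  feddes: {h1: 0.0, h2: -0.01, h3_high: -5.00, h3_low: -9.00, h4: -160.0}
  t_high: 5.0
  t_low: 1.0
  osmotic: {ec_threshold: 16.0, slope_pct: 2.5}
  kc: {ini: 0.3, mid: 1.15, end: 0.25}
  stage_fractions: [0.25, 0.25, 0.30, 0.20]
  # literature LAI trajectory: 0.29 -> 3.5 m2 m-2, senescing at end of season
  lai_points: [[0.0, 0.29], [0.50, 3.5], [0.80, 3.5], [1.0, 0.29]]
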