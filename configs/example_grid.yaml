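# Example grid configuration for analysis/05_experiments.py --config.
# Scenario presets referenced by label carry CO2 concentrations taken from
# the published RCP concentration tables (Meinshausen et al. 2011, 20-year
# means): RCP4.5-2050 487 ppm, RCP8.5-2050 541 ppm, RCP4.5-2090 532 ppm,
# RCP8.5-2090 845 ppm.  Override co2_ppm via scenario_specs if needed.
site:
  latitude: 31.5
climatology:
  temp_noise: 2.2
soil:
  theta_fc: 0.32
  theta_wp: 0.17
  theta_sat: 0.45
  ksat: 100.0
crop:
  wp_star: 15.0
  hi0: 0.48
management:
  irrigate: true
  trigger_fraction: 0.5   # refill when root-zone depletion exceeds 0.5 TAW
experiments:
  n_years: 20
  start_year: 1991
  seed: 1
  n_pseudo_models: 5
  scenarios: [RCP4.5-2050, RCP8.5-2050, RCP4.5-2090, RCP8.5-2090]
  sowings: [early, intermediate, late]
  members: [mean, mean_plus_sd, mean_minus_sd]
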