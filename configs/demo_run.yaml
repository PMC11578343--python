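# Small end-to-end demo: simulate three cells in the standard four-zone
# device, then detect, fit and summarise.
geometry: four_zone_geometry.yaml
seed: 7
simulation:
  n_cells: 3
  noise_sd: 1.0e-4        # white noise, relative to baseline resistance
  baseline_drift_amp: 0.005
  event_rate_per_hour: 1440.0
pipeline: {}
rheology: {}
log_level: INFO
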