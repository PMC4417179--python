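# Calibrated ED2.8 cohort at 50 mM NaCl: ~1000 molecules recorded for
# 50 min at 0.5 s per frame. Rates are calibrated from the measured mean
# dwell times and relative populations under the mid-centered scheme
# (high <-> mid <-> low). Run with:
#   gapekin run --config examples/paper_cohort.yaml --out runs/ed28 --seed 1
cohort:
  n_molecules: 1000
  duration_s: 3000.0
  frame_period_s: 0.5
  salt_mM: 50.0
  free_dna_fraction: 0.0
  seed: 1
rates:
  connectivity: mid_centered
  mean_dwells: {high: 100.25, mid: 418.6, low: 42.48}
  occupancies: {high: 0.1183, mid: 0.8471, low: 0.0346}
emission:
  state_fret: {high: 0.545, mid: 0.440, low: 0.339}
  total_intensity: 220.0
  noise_sd: 12.0
  leakage: 0.12
  gamma: 1.7
  background_donor: 10.0
  background_acceptor: 10.0
  frame_period: 0.5
correction:
  leakage: 0.12
  gamma: 1.7
segmentation:
  method: threshold
  median_window: 5
  min_dwell_frames: 12
kinetics:
  fit_states: [high]
  n_boot: 1000
histograms:
  bin_width: 0.02
  window_frames: 10
structure:
  r0_nm: 5.9
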