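# Fully-populated demo profile: ten batches at the default study conditions.
seed: 1
outdir: scratch/demo_run
stages: [simulate, peaks, fingerprint, quantify, annotate]
log_level: INFO

generator:
  n_batches: 10
  nominal_total: 50.0      # mg/ml total saponins in the injection
  dilution_to: 0.5         # mg/ml in the assay solution
  rt_jitter_sd: 0.05       # min, shared per-batch retention shift
  rt_jitter_peak_sd: 0.005 # min, independent per-peak scatter
  area_cv: 0.05            # relative SD of peak areas across batches
  peak_width_sd: 0.04      # min, Gaussian sigma of the EMG peaks
  emg_tau: 0.03            # min, exponential tail constant
  baseline_amplitude: 5.0  # slow drift amplitude
  noise_sd: 0.5            # white detector noise SD
  solvent_front: 60.0      # amplitude of the 0-28 min disturbance

peaks:
  min_area: 1.0
  baseline_window: 2.0
  window: [28.0, 75.0]

fingerprint:
  rt_tolerance: 0.3
  align: true
  metric: cosine

quantify:
  nominal_total: 50.0
  assay_total: 0.5

annotate:
  tolerance: 2.0
  rt_window: 1.0
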