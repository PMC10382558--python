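# Demo pipeline: simulate single-channel records across the pH-buffer
# series, idealize, accumulate the titration table, and refit K_H / K_OC.
# Protonation kinetics are slowed (rate_scale) so sub-state dwells are
# long relative to the 1 kHz analysis bandwidth.
n_sites: 4
K_H: 2.0e-7
K_OC: 0.05
rate_scale: 3.0e-3
lambda_c: 3.7
noise_sd: 0.42
voltage: -120.0
full_conductance: 60.0
pH_grid: [6.2, 6.5, 6.8, 7.1, 7.4, 7.7, 8.0]
duration: 60.0
seed: 7
out_dir: demo_run
figures: true
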