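# Demo: simulate a small two-layer coral-like phantom and process it.
#
#   isoct simulate -c examples/demo.yaml -o scratch/demo_scan.h5
#   isoct process scratch/demo_scan.h5 -c examples/demo.yaml -o scratch/demo_out
#   isoct report scratch/demo_out
#
# Sized to run end-to-end in well under two minutes on one CPU.
acquisition:
  n_k: 1024
  lateral_shape: [16, 16]
  snr_db: 30.0
  rng_seed: 1234
  rolloff_db_per_mm: -10.0
phantom:
  surface_depth_um: 100.0
  layers:
    - thickness_um: 150.0
      D: 2.5
      Ln_nm: 1000.0
      mu_s_600_cm1: 150.0
      chl_volumetric_mg_cm3: 0.3
      kind: tissue
    - thickness_um: 100.0
      D: 3.5
      Ln_nm: 500.0
      mu_s_600_cm1: 250.0
      kind: skeleton
fit:
  decompose_block: 8
stft:
  z_max_um: 470.0
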