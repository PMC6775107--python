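# Calibration standard: a Rayleigh-type scatterer suspension (small
# correlation length, known backscatter spectrum), scanned with the same
# acquisition settings as the demo phantom.  Used via:
#
#   isoct simulate -c examples/reference.yaml -o scratch/ref_scan.h5
#   isoct process scratch/demo_scan.h5 -c examples/demo.yaml \
#       -o scratch/demo_out --reference scratch/ref_scan.h5
acquisition:
  n_k: 1024
  lateral_shape: [16, 16]
  snr_db: 30.0
  rng_seed: 77
  rolloff_db_per_mm: -10.0
phantom:
  surface_depth_um: 100.0
  layers:
    - thickness_um: 240.0
      D: 4.0
      Ln_nm: 20.0
      mu_s_600_cm1: 30.0
      kind: tissue
stft:
  z_max_um: 470.0
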