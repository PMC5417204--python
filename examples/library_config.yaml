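seed: 2026
replicates: 3
noise:
  baseline_offset_sd: 0.02
  baseline_slope_sd: 5.0e-05
  batch_effect_sd: 0.03
  scan_noise_sd: 0.0002
brands:
- name: EXAMPLE
  components:
    api:
      nominal: 1.0
      bands:
      - center: 880
        width: 10
        amplitude: 0.9
      - center: 940
        width: 12
        amplitude: 0.5
  excipient_bands:
  - center: 790
    width: 55
    amplitude: 0.3
  - center: 955
    width: 80
    amplitude: 0.4
  quality_assured:
    batches: 2
    samples: 4
  falsified:
    batches: 1
    samples: 1
    mode: wrong_compound
    shift_nm: 60
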