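seed: 1
simulate: true
analysis:
  n_perm: 1000
  n_boot: 500
  resample_counts: [10, 50, 100, 250, 500]
  resample_reps: 100
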