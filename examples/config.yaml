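# Two reconstituted-ring conditions plus two coupled-assay samples.
seed: 1
output_dir: ringfrap_out
conditions:
  - label: ring_slow
    simulation:
      n_cells: 12
      c_eq1: 0.15
      c_eq2: 0.85
      koff1: 0.01
      koff2: 0.0002
      r: 0.1
  - label: ring_dynamic
    simulation:
      n_cells: 12
      c_eq1: 0.15
      c_eq2: 0.85
      koff1: 0.01
      koff2: 0.003
      r: 0.1
comparison:
  method: welch_t
gtpase:
  - label: assay_a
    turnover_per_min: 0.39
    ftsz_conc_molar: 5.0e-6
    noise_sd_AU: 0.002
  - label: assay_b
    turnover_per_min: 0.26
    ftsz_conc_molar: 5.0e-6
    noise_sd_AU: 0.002
plots: false
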