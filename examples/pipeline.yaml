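# End-to-end run on simulated data: adjust or replace the simdata section
# with your own matrices via the stage CLIs.
io:
  outdir: results/
simdata:
  seed: 7
  n_proteins: 2000
  n_phosphosites: 1000
  frac_de: 0.1
  effect_log2fc: 2.0
  noise_sd: 0.5
preprocess:
  imputation: half-minimum
  min_nonmissing_per_group: 2
diffabund:
  mode: fdr_and_fc
  sd_multiple: 2.0
  fdr_cut: 0.05
  n_perm: 70
kinases:
  n_top: 200
  pu_rounds: 50
comodules:
  min_size: 100
  merge_cut: 0.25
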