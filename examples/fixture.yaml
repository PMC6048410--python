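# Packaged 40-sample synthetic fixture for end-to-end runs.
seed: 11
outdir: scratch/fixture_run
simulate:
  n_samples: 40
  n_background_genes: 100
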