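# Study configuration for the synthetic analysis drivers (01-06).
# The cohort sizes here keep the full narrative run to a few minutes on one
# CPU; statistical conditions (mixture, noise, replicate design) are the
# package defaults.
simulation:
  n_genes: 150
  frac_positives: 0.3
  positive_shift_mean: 1.5
  seed: 7
sam:
  n_perm: 200
  fdr_cutoff: 0.05
deconvolution:
  reference_sizes: [25, 40]
sre:
  n_genes_scored: 60
  n_samples: 200
  # altered-invariant-nucleotide loops; second-position variants (CAGG,
  # CCGG, ...) are subsets of the CNGG consensus and would be collinear
  # with it in the regression
  variants: ["ANGG", "CNAG", "CNGA"]
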