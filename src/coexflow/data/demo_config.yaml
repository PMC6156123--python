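# Packaged demo configuration: a down-scaled synthetic study with the full
# 2-population x 3-individual x 5-organ design and every planted signal.
simulate:
  n_transcripts: 400
  n_individuals_per_pop: 3
  frac_uet_A: 0.05
  frac_uet_B: 0.05
  frac_det: 0.10
  det_fold_change: 4.0
  n_modules: 2
  module_size: 45
  module_correlation: 0.8
  n_go_terms: 20
  seed: 0
fdr: 0.05
min_fc: 1.5
hrr_candidate: 30
hrr_report: 3
hcca_min_size: 40
hcca_max_size: 200
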