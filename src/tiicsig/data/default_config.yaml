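# Default pipeline configuration. Every analysis default is explicit here
# so that deviations show up as visible diffs.

radii_um: [10, 20, 30]            # effective-score radii
effective_density_radius_um: 20
signature_radius_um: 20           # radius of the signature's spatial component
tertile_split: two_thirds         # high = strictly above the 2/3 quantile
score_cut: median                 # prognostic-score high/low cut-point

response_models:
  families: [etc, gbc, abc, mlp]
  folds: 3
  repetitions: 5000
  fast_repetitions: 200
  default_params: true            # false => grid search within training folds

simulate:
  n_patients: 20
  rois_per_patient: {TC: 3, IM: 1, N: 1}
  clustering: poisson
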