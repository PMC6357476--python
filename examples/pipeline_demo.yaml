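# Demo pipeline: simulate a small cross-section image set, a balanced
# trait trial and a read pileup, then measure, analyse and QC them.
simulate_image:
  n_images: 2
  height_px: 256
  width_px: 256
  scale_cm_per_px: 0.005
  stalk_semi_axes_cm: [0.55, 0.50]
  rind_thickness_cm: 0.15
  bundle_count: 10
  bundle_min_spacing_cm: 0.12

simulate_traits:
  n_genotypes: 120
  n_environments: 3
  n_replications: 2
  grand_mean: 47.8
  var_G: 2.0
  var_E: 0.5
  var_RwithinE: 0.25
  var_GE: 0.5
  var_e: 1.0

simulate_pileup:
  n_sites: 60
  n_individuals: 30
  mean_depth: 10
  true_allele_freqs: 0.3
  error_rate: 0.01

geno_qc:
  site_class: reference
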