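# Desk-scale source/target pair with covariate shift AND label gap:
# blue medium cells counting 3-8  ->  red smaller haloed cells counting 6-12.
source:
  image_size: 64
  count_range: [3, 8]
  blob_radius_range: [4.0, 6.0]
  blob_color: [0.15, 0.25, 0.85]
  halo: false
  seed: 1000
appearance_shift:
  blob_color: [0.85, 0.20, 0.20]
  halo: true
  blob_radius_range: [3.0, 4.5]
label_gap_shift:
  count_range: [6, 12]
target_seed: 1000
n_per_domain: 300
split_fracs: [0.55, 0.20, 0.25]
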