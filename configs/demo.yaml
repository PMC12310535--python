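seed: 5
map: toy
sim:
  founders_per_clan: 4
  generations: 3
  endogamy_prob: 0.8
  offspring_mean: 2.4
  n_sites: 3000
  missing_rate: 0.3
  error_rate: 0.005
kinship:
  window_bp: 5000000
  min_overlap: 10
clanstats:
  n_perm: 999
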