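{
  "pct_all_home_experiments": 63.6,
  "pct_household": 87.2,
  "pct_healthier_than_yeast": 84.2,
  "mean_ph_home_minus_lab": 0.73,
  "pcoa_pc12_pct": 13.7,
  "n_samples_collected": 671,
  "pct_bakery_age_gt5": 55.0
}
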