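# Full pipeline configuration for `mobifood all --config examples/config.yaml`.
# Omitted keys fall back to the study defaults (50 m roaming distance,
# 5 min / 2 events per stay, 200 m attribution radius, daily periods at
# 11:00 and 16:00, night window 22:00-06:00, min 5 users per neighborhood).
seed: 1
world:
  n_neighborhoods: 12
  grid_cell_km: 2.0
  n_tracts_per_neighborhood: 4
  n_poi_per_neighborhood: 30
  ff_fraction_range: [0.08, 0.25]
  n_users: 240
  n_respondents: 3000
  days: 7
  ping_interval_min_range: [5.0, 15.0]
  ping_accuracy_median_m: 21.0
  period_dropout_prob: 0.2
  seed: 1
stay:
  d_roam_m: 50.0
  min_duration_min: 5.0
  min_events: 2
attribution:
  d_max_m: 200.0
min_users: 5
trips_scaling: identity
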