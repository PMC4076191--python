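# Default model constants. Each value carries a provenance tag:
#   PAPER          - printed in the source study
#   PAPER-APPENDIX - lives in a supplementary appendix not reproduced here;
#                    the shipped number is a placeholder of the right order
#                    of magnitude and must be transcribed for real use
#   DECISION       - a documented implementation choice

energetics:
  a_max_intake: 61.3        # g/day per kg body mass, Michaelis-Menten asymptote [PAPER]
  b_half_saturation: 40.0   # g/m^2, biomass at half-maximal intake [PAPER]
  energy_per_gram: 7.79     # kJ/g dry lichen [PAPER]
  body_mass: 100.0          # kg, adult female order of magnitude [DECISION]
  step_hours: 4.0           # h, GPS fix interval [PAPER]
  bmr_per_step: 1540.0      # kJ per 4 h step [PAPER-APPENDIX placeholder]
  c_dist: 0.26              # kJ per metre travelled [PAPER-APPENDIX placeholder]
  c_climb: 2.5              # kJ per metre climbed (descent free) [PAPER-APPENDIX placeholder]
  ledger_steps: 18          # steps in the 72 h energy window [PAPER]

memory:
  patch_radius: 1600.0      # m, in-patch distance to a cluster centroid [PAPER]
  capacity: 15              # max remembered clusters K_mem [DECISION]
  m_consec: 2               # consecutive close off-patch locations that seed a cluster [DECISION]

disturbance:
  # zero-crossing distances of the linear kernel f(D) = max(0, 1 - D/D0) [PAPER]
  road: 1500.0
  recent_cut: 1600.0
  regenerating_cut: 1300.0

landscape:
  cell_size: 25.0           # m [PAPER]
  quadrat_area_km2: 225.0   # scenario quadrat size [PAPER]
  converted_fraction: 0.70  # encroachment conversion fraction [PAPER]
  target_class: 12          # mixed/deciduous forest [PAPER]
  protected_classes: [1, 3] # fixed open areas, water [PAPER]
  recent_cut_max_age: 5     # years before recent -> regenerating [PAPER]

# Per-class lichen biomass (g/m^2) and canopy cover (%). Class codes follow the
# 15-class legend: 1 fixed open, 2 burned, 3 water, 4 heath w/o lichen,
# 5 heath w/ lichen, 6 wetland, 7 regenerating mixed, 8 regenerating conifer,
# 9 open conifer w/o lichen, 10 dense mature conifer, 11 open conifer w/ lichen,
# 12 mixed/deciduous, 13 regenerating cut, 14 recent cut, 15 road.
# Biomass values are SYNTHETIC placeholders [PAPER-APPENDIX]: the cited field
# estimates are not printed in the source.
classes:
  1:  {name: fixed_open,             lichen: 10.0, cover: 0.0}
  2:  {name: burned,                 lichen: 2.0,  cover: 5.0}
  3:  {name: water,                  lichen: 0.0,  cover: 0.0}
  4:  {name: heath_no_lichen,        lichen: 0.0,  cover: 5.0}
  5:  {name: heath_lichen,           lichen: 40.0, cover: 5.0}
  6:  {name: wetland,                lichen: 5.0,  cover: 10.0}
  7:  {name: regen_mixed,            lichen: 2.0,  cover: 40.0}
  8:  {name: regen_conifer,          lichen: 5.0,  cover: 40.0}
  9:  {name: open_conifer_no_lichen, lichen: 0.0,  cover: 30.0}
  10: {name: dense_mature_conifer,   lichen: 5.0,  cover: 80.0}
  11: {name: open_conifer_lichen,    lichen: 60.0, cover: 30.0}
  12: {name: mixed_deciduous,        lichen: 1.0,  cover: 70.0}
  13: {name: regenerating_cut,       lichen: 2.0,  cover: 20.0}
  14: {name: recent_cut,             lichen: 1.0,  cover: 5.0}
  15: {name: road,                   lichen: 0.0,  cover: 0.0}

estimation:
  n_random_steps: 20        # controls per stratum [PAPER]
  block_len: 24             # strata per independence block (4 days) [DECISION]
  gap_steps: 2              # dropped strata between blocks (8 h) [PAPER]
  proximity_m: 100.0        # cross-individual merge distance [PAPER]
  cv_folds: 5               # [PAPER]
  cv_reps: 100              # [PAPER]

simulation:
  n_candidates: 21          # candidate steps per iteration [PAPER]
  steps_per_day: 6          # [PAPER]
  winter_start: "12-28"     # Dec 28 [PAPER]
  winter_end: "04-15"       # Apr 15 [PAPER]
  selection_method: best90
  best90_exploit: 0.9       # [PAPER]

validation:
  mcp_trim: 0.05            # fraction of farthest points dropped [PAPER]
  rsf_random_per_used: 10   # available points per used point [DECISION]
  reference_class: 9        # open conifer stand without lichen [PAPER]
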