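# California Gnatcatcher (Polioptila californica) life history, best
# habitat (q = 1). Vital rates are annual; the habitat exponents shape
# the quality coefficient c = 1 - (1 - q)^alpha. daily_nest_survival is
# calibrated so unexposed seasonal fecundity equals f = 2.26 female
# offspring/female (see avirisk.nest.calibrate_fixture).
name: cagn
s_j: 0.4314
s_a: 0.52
f: 2.26
alpha_f: 3.0
alpha_s: 5.0
breeding:
  season_start: 84      # late March, day-of-year
  season_end: 196       # mid-July: end of the nest-initiation window
  laying_days: 4
  incubation_days: 14
  nestling_days: 16
  clutch_size: 4
  prop_female: 0.5
  daily_nest_survival: 0.956711
  wait_after_failure: 3
  wait_after_success: 21
  nest_initiation_prob: 1.0
forager:
  body_weight: 6.0            # g
  frac_diet_on_field: 1.0     # TIM female uses the treated field; patch
                              # crop proportion dilutes at landscape level
  field_fidelity: 0.7
  diet_class: small insects
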