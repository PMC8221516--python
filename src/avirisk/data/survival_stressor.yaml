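# Acute ("survival stressor") insecticide: registration-study endpoints
# and label constraints. LD50 test species: northern bobwhite (178 g).
name: survival_stressor
ld50: 359.0             # mg a.i./kg body weight
ld50_bw_test: 178.0     # g, northern bobwhite
lc50: 3497.0            # mg a.i./kg diet
noael_diet: 358.0       # mg a.i./kg diet, reproductive endpoint
max_seasonal_rate: 3.0  # lbs a.i./acre per season
min_interval: 7         # days between applications
ld50_scaling_factor: 1.15
foliar_half_life: 35.0  # days
probit_slope: 4.5
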