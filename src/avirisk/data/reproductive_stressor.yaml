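# Chronic ("reproductive stressor") insecticide: registration-study
# endpoints and label constraints. LD50 test species: mallard (1170 g).
# No foliar dissipation estimate was available, so the conventional
# 35-day default half-life is used.
name: reproductive_stressor
ld50: 5000.0            # mg a.i./kg body weight
ld50_bw_test: 1170.0    # g, mallard
lc50: 2354.0            # mg a.i./kg diet
noael_diet: 4.62        # mg a.i./kg diet, reproductive endpoint
max_seasonal_rate: 0.03 # lbs a.i./acre per season
min_interval: 5         # days between applications
ld50_scaling_factor: 1.15
foliar_half_life: 35.0  # days
probit_slope: 4.5
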