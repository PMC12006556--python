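# UK general-population time-trade-off valuation set for EQ-5D-3L
# (MVH study, York). Score = 1 - any_problem - sum(level decrements) - n3.
name: uk_tto_mvh
full_health_constant: 1.0
any_problem_decrement: 0.081
n3_decrement: 0.269
dimensions:
  mobility:
    level2: 0.069
    level3: 0.314
  self_care:
    level2: 0.104
    level3: 0.214
  usual_activities:
    level2: 0.036
    level3: 0.094
  pain_discomfort:
    level2: 0.123
    level3: 0.386
  anxiety_depression:
    level2: 0.071
    level3: 0.236
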