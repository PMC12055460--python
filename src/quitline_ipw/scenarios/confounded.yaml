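name: confounded
n: 10000
seed: 20200402
covariates:
- name: age
  kind: continuous
  mean: 48.29
  sd: 14.95
  lower: 18
  upper: 94
- name: gender
  kind: categorical
  levels:
  - Female
  - Male
  counts:
  - 2631
  - 2064
- name: race_eth
  kind: categorical
  levels:
  - NH_White
  - NH_Black
  - NH_AIAN
  - NH_Other
  - Hispanic
  counts:
  - 3307
  - 385
  - 446
  - 354
  - 203
- name: income
  kind: categorical
  levels:
  - lt_10k
  - 10k_14k
  - 15k_19k
  - 20k_24k
  - 25k_34k
  - 35k_49k
  - 50k_plus
  counts:
  - 1462
  - 770
  - 531
  - 448
  - 519
  - 472
  - 493
- name: insurance
  kind: categorical
  levels:
  - Private
  - Medicaid
  - Medicare
  - Other_public
  - Uninsured
  counts:
  - 1008
  - 923
  - 1019
  - 227
  - 1518
- name: geography
  kind: categorical
  levels:
  - Rural
  - Micropolitan
  - Metropolitan
  counts:
  - 755
  - 1017
  - 2923
- name: ttfu
  kind: categorical
  levels:
  - within_5min
  - min_6_30
  - min_31_60
  - over_60min
  counts:
  - 2199
  - 1663
  - 494
  - 339
- name: products
  kind: categorical
  levels:
  - Multiple
  - Cigarettes
  - Smokeless
  - Other
  counts:
  - 516
  - 3665
  - 353
  - 161
- name: regmode
  kind: categorical
  levels:
  - Phone
  - Online
  - Referral_other
  counts:
  - 3017
  - 1269
  - 409
treatment_model:
  intercept: 0.5656
  terms:
    age: 0.022
    insurance:Private: -0.35
    insurance:Medicare: 0.35
    insurance:Medicaid: 0.15
    income:50k_plus: -0.45
    income:35k_49k: -0.25
    income:25k_34k: -0.15
    income:lt_10k: 0.1
    income:10k_14k: 0.1
    income:15k_19k: 0.15
censoring_model:
  intercept: 0.1826
  terms:
    A: -0.4291
    age: -0.013
    race_eth:NH_White: 0.18
    race_eth:NH_Black: -0.2
    insurance:Uninsured: 0.28
    insurance:Medicare: -0.15
    geography:Rural: 0.18
outcome_model:
  intercept: -1.1511
  terms:
    A: 0.20701
    age: 0.006
    insurance:Uninsured: -0.15
    insurance:Private: 0.1
    insurance:Medicare: 0.05
    income:50k_plus: 0.12
    income:35k_49k: 0.08
    income:lt_10k: -0.08
    ttfu:within_5min: -0.15
    ttfu:over_60min: 0.12
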