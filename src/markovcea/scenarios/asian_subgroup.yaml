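schema_version: 1
settings:
  cycle_days: 21.0
  horizon_years: 5.0
  annual_discount_rate: 0.03
  wtp_per_qaly: 36000.0
  gdp_per_capita: 12000.0
  initial_distribution:
    SD: 1.0
    RE: 0.0
    PD: 0.0
    DE: 0.0
  half_cycle_correction: true
  rounding_mode: published_3dp
strategies:
- name: neratinib+capecitabine
  clinical:
    rr: null
    os_months: 23.8
    pfs_months: 7.0
    dor_months: 11.1
  utilities:
    stable: 0.74
    remission: 0.85
    relapse: 0.5
    death: 0.0
    extras:
      no_recurrence_post_chemo: 0.94
      local_recurrence_year1: 0.74
  costs:
    bsa_m2: 1.67
    dosing:
    - drug: neratinib
      dose_mg: 240.0
      unit_mg: 40.0
      unit_price: 13.46
      admin_per_day: 1
      days_per_cycle: 21
      per_m2: false
    - drug: capecitabine
      dose_mg: 1500.0
      unit_mg: 150.0
      unit_price: 0.6
      admin_per_day: 2
      days_per_cycle: 14
      per_m2: true
    loperamide:
      unit_price: 0.23
      initial_doses: 2
      intensive_days: 3
      intensive_doses_per_day: 6
      maintenance_days: 18
      maintenance_doses_per_day: 4
    ae_profile:
    - event: diarrhea
      incidence: 0.307
      cost_per_event: 4083.63
    - event: ppe_syndrome
      incidence: 0.12
      cost_per_event: 2316.0
    - event: vomiting
      incidence: 0.05
      cost_per_event: 945.63
    - event: fatigue
      incidence: 0.037
      cost_per_event: 1158.04
    - event: anemia
      incidence: 0.024
      cost_per_event: 7350.98
    other_costs:
    - name: hospitalization
      annual_amount: 3200.0
      states:
      - PD
    - name: concomitant_medications
      annual_amount: 2176.0
      states:
      - PD
    - name: health_examinations
      annual_amount: 4552.0
      states:
      - SD
      - RE
  sa_ranges:
    p_stable_remission:
    - 0.189
    - 0.231
    p_stable_relapse:
    - 0.162
    - 0.198
    p_remission_relapse:
    - 0.0405
    - 0.0495
    p_relapse_death:
    - 0.027
    - 0.033
    p_stable_stable:
    - 0.5490000000000002
    - 0.6710000000000002
    p_remission_remission:
    - 0.8594999999999999
    - 1.0
    p_relapse_relapse:
    - 0.873
    - 1.0
    u_stable:
    - 0.592
    - 0.888
    u_remission:
    - 0.68
    - 1.0
    u_relapse:
    - 0.4
    - 0.6
    cost_ae_diarrhea:
    - 3675.267
    - 4491.993
    cost_ae_ppe_syndrome:
    - 2084.4
    - 2547.6
    cost_ae_vomiting:
    - 851.067
    - 1040.193
    cost_ae_fatigue:
    - 1042.236
    - 1273.844
    cost_ae_anemia:
    - 6615.882
    - 8086.078
    cost_hospitalization:
    - 2880.0
    - 3520.0
    cost_concomitant_medications:
    - 1958.4
    - 2393.6
    cost_health_examinations:
    - 4096.8
    - 5007.2
    price_capecitabine:
    - 0.54
    - 0.66
    price_neratinib:
    - 12.114
    - 14.806
    price_loperamide:
    - 0.207
    - 0.253
  distributions:
    p_stable_remission: beta
    p_stable_relapse: beta
    p_remission_relapse: beta
    p_relapse_death: beta
    p_stable_stable: beta
    p_remission_remission: beta
    p_relapse_relapse: beta
    u_stable: beta
    u_remission: beta
    u_relapse: beta
    cost_ae_diarrhea: gamma
    cost_ae_ppe_syndrome: gamma
    cost_ae_vomiting: gamma
    cost_ae_fatigue: gamma
    cost_ae_anemia: gamma
    cost_hospitalization: gamma
    cost_concomitant_medications: gamma
    cost_health_examinations: gamma
    price_capecitabine: gamma
    price_neratinib: gamma
    price_loperamide: gamma
- name: lapatinib+capecitabine
  clinical:
    rr: null
    os_months: 18.7
    pfs_months: 5.4
    dor_months: 4.2
  utilities:
    stable: 0.74
    remission: 0.85
    relapse: 0.5
    death: 0.0
    extras:
      no_recurrence_post_chemo: 0.94
      local_recurrence_year1: 0.74
  costs:
    bsa_m2: 1.67
    dosing:
    - drug: lapatinib
      dose_mg: 1250.0
      unit_mg: 250.0
      unit_price: 16.12
      admin_per_day: 1
      days_per_cycle: 21
      per_m2: false
    - drug: capecitabine
      dose_mg: 2000.0
      unit_mg: 150.0
      unit_price: 0.6
      admin_per_day: 2
      days_per_cycle: 14
      per_m2: true
    loperamide: null
    ae_profile:
    - event: diarrhea
      incidence: 0.143
      cost_per_event: 4083.63
    - event: ppe_syndrome
      incidence: 0.138
      cost_per_event: 2316.0
    - event: vomiting
      incidence: 0.024
      cost_per_event: 945.63
    - event: fatigue
      incidence: 0.04
      cost_per_event: 1158.04
    - event: anemia
      incidence: 0.044
      cost_per_event: 7350.98
    other_costs:
    - name: hospitalization
      annual_amount: 3200.0
      states:
      - PD
    - name: concomitant_medications
      annual_amount: 2176.0
      states:
      - PD
    - name: health_examinations
      annual_amount: 4552.0
      states:
      - SD
      - RE
  sa_ranges:
    p_stable_remission:
    - 0.18989999999999999
    - 0.2321
    p_stable_relapse:
    - 0.4176
    - 0.5104000000000001
    p_remission_relapse:
    - 0.1044
    - 0.12760000000000002
    p_relapse_death:
    - 0.0342
    - 0.041800000000000004
    p_stable_stable:
    - 0.29250000000000004
    - 0.35750000000000004
    p_remission_remission:
    - 0.7956
    - 0.9724
    p_relapse_relapse:
    - 0.8658
    - 1.0
    u_stable:
    - 0.592
    - 0.888
    u_remission:
    - 0.68
    - 1.0
    u_relapse:
    - 0.4
    - 0.6
    cost_ae_diarrhea:
    - 3675.267
    - 4491.993
    cost_ae_ppe_syndrome:
    - 2084.4
    - 2547.6
    cost_ae_vomiting:
    - 851.067
    - 1040.193
    cost_ae_fatigue:
    - 1042.236
    - 1273.844
    cost_ae_anemia:
    - 6615.882
    - 8086.078
    cost_hospitalization:
    - 2880.0
    - 3520.0
    cost_concomitant_medications:
    - 1958.4
    - 2393.6
    cost_health_examinations:
    - 4096.8
    - 5007.2
    price_capecitabine:
    - 0.54
    - 0.66
    price_lapatinib:
    - 14.508
    - 17.732
  distributions:
    p_stable_remission: beta
    p_stable_relapse: beta
    p_remission_relapse: beta
    p_relapse_death: beta
    p_stable_stable: beta
    p_remission_remission: beta
    p_relapse_relapse: beta
    u_stable: beta
    u_remission: beta
    u_relapse: beta
    cost_ae_diarrhea: gamma
    cost_ae_ppe_syndrome: gamma
    cost_ae_vomiting: gamma
    cost_ae_fatigue: gamma
    cost_ae_anemia: gamma
    cost_hospitalization: gamma
    cost_concomitant_medications: gamma
    cost_health_examinations: gamma
    price_capecitabine: gamma
    price_lapatinib: gamma
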