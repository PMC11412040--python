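config:
  horizon_days: 365.0
  cycle_exponent_K: 3.4750083
  hosp_episode_days: 11.7
  outpt_episode_days: 30.0
  n_patients: 1000000
  seed: 2022
  wtp: 250832.40
  psa_iterations: 1000
  psa_se_fraction_prob: 0.10
  psa_se_fraction_cost: 0.20
  owsa_range_fraction: 0.20
  stable_care_scale: 0.0
groups:
  olanzapine: [olanzapine_odt, olanzapine_sot]
  risperidone: [risperidone_odt, risperidone_sot]
  aripiprazole: [aripiprazole_odt, aripiprazole_sot]
strategies:
  olanzapine_sot: {formulation: SOT, daily_drug_cost_mad: 9.7}
  risperidone_sot: {formulation: SOT, daily_drug_cost_mad: 9.6}
  aripiprazole_sot: {formulation: SOT, daily_drug_cost_mad: 10.6}
  olanzapine_odt: {formulation: ODT, daily_drug_cost_mad: 11.0}
  risperidone_odt: {formulation: ODT, daily_drug_cost_mad: 19.4}
  aripiprazole_odt: {formulation: ODT, daily_drug_cost_mad: 13.7}
mpr_by_category: {compliant: 0.90, partial: 0.70, non: 0.40}
files:
  adherence: adherence.csv
  relapse: relapse.csv
  adverse_events: adverse_events.csv
  utilities: utilities.csv
  resources: resources.csv
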