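# Commercial payer perspective, replication configuration: per-patient
# hospitalization, ED and SABA baselines are overridden with the published
# per-patient dollar values, and an explicit reconciliation line makes
# category sums match the published monitored-arm total. All costs 2020 USD.
payer: commercial
population:
  plan_size: 5000000
  age_shares: {under_40: 0.53, age_40_64: 0.35, age_65_plus: 0.12}
prevalence: {age_40_64: 0.076, age_65_plus: 0.132}
gold_distribution: {A: 0.534, B: 0.267, C: 0.082, D: 0.117}
hcru:
  outpatient_visits: {A: 2.64, B: 2.64, C: 2.64, D: 2.64}
  ed_visits: {A: 0.11, B: 0.19, C: 0.22, D: 0.22}
  hospitalizations: {A: 0.36, B: 0.46, C: 0.56, D: 0.56}
  readmissions: {A: 0.04, B: 0.07, C: 0.08, D: 0.08}
unit_costs:
  office_outpatient_visit: 126.0
  ed_visit: 3065.0
  hospitalization: 25839.0
saba:
  # GOLD A and C map to the low-symptom CAT bands, hence equal puff rates.
  weekly_puffs: {A: 5.81, B: 8.82, C: 5.81, D: 12.78}
  actuations_per_canister: 200
  annual_cost_override: 292.0
  wac_prices:
    - {label: Albuterol sulfate HFA, price: 35.98}
    - {label: Albuterol sulfate HFA (Cipla), price: 57.75}
    - {label: Proair Digihaler, price: 146.67}
    - {label: Proair HFA, price: 66.88}
    - {label: Proair Respiclick, price: 62.52}
    - {label: Proventil HFA, price: 79.73}
    - {label: Ventolin HFA, price: 55.36}
    - {label: Atrovent HFA, price: 332.70}
    - {label: Combivent Respimat, price: 426.45}
    - {label: Albuterol/ipratropium, price: 426.45}
controller:
  daily_costs:
    LAMA: 14.80
    LABA: 10.40
    LABA_ICS: 10.50
    LABA_LAMA: 17.14
    LABA_LAMA_ICS: 19.11
  mix:
    A: {LAMA: 0.40, LABA: 0.20, LABA_LAMA: 0.40}
    B: {LAMA: 0.30, LABA_ICS: 0.30, LABA_LAMA: 0.40}
    C: {LABA_ICS: 0.60, LABA_LAMA: 0.35, LABA_LAMA_ICS: 0.05}
    D: {LABA_ICS: 0.40, LABA_LAMA: 0.10, LABA_LAMA_ICS: 0.50}
  pdc: {A: 0.54, B: 0.60, C: 0.56, D: 0.62}
rtm:
  - {code: "98975", annual_frequency: 1, fee: 19.38}
  - {code: "98976", annual_frequency: 6, fee: 55.72}
  - {code: "98980", annual_frequency: 6, fee: 50.18}
effects:
  hosp_reduction: 0.30
  ed_reduction: 0.55
  saba_reduction: 0.594
  subscription_cost: 200.0
  bill_rtm_for_all_enrolled: true
uptake: [0.10, 0.15, 0.30]
settings:
  days_per_year: 365.25
  reconciliation_line: 73.0
baseline_cost_overrides:
  hospitalizations: 9918.0
  ed_visits: 462.0
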