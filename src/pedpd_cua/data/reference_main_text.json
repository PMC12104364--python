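{
  "description": "Model inputs printed in the main text of the source analysis (Thai pediatric ESKD setting, 2022 baht).",
  "utilities": {
    "u_APD": 0.94,
    "u_CAPD": 0.89
  },
  "discount_rate_costs": 0.03,
  "discount_rate_outcomes": 0.03,
  "start_age": 1,
  "wtp": 160000,
  "budget_impact": {
    "annual_cost_capd": 433641,
    "annual_cost_apd": 496836,
    "proportion_pediatric": 0.004,
    "proportion_pd": 0.76,
    "p_kt": 0.079,
    "p_hd": 0.031,
    "p_death": 0.023,
    "incident_cases_2021": 61,
    "uptake": 1.0,
    "years": [2023, 2024, 2025, 2026, 2027, 2028, 2029, 2030, 2031, 2032],
    "patient_counts": [618, 671, 724, 778, 831, 884, 937, 990, 1043, 1051]
  }
}
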