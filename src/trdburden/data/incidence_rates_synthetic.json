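{
  "description": "Synthetic mean age-specific annual incidence of newly diagnosed depression (per person-year), reverse-engineered from the aggregate rate of 15.0 per 10,000 population; not observed data.",
  "rates": {
    "10-14": 0.0015,
    "15-19": 0.0015,
    "20-24": 0.0015,
    "25-29": 0.0015,
    "30-34": 0.0015,
    "35-39": 0.0015,
    "40-44": 0.0015,
    "45-49": 0.0015,
    "50-54": 0.0015,
    "55-59": 0.0015,
    "60-64": 0.0015,
    "65-69": 0.0015,
    "70-74": 0.0015,
    "75-79": 0.0015,
    "80-84": 0.0015,
    "85+": 0.0015
  }
}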