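{
  "description": "Synthetic age-specific uplift profile for extra 2023 cases (aggregate +25%), calibrated so 2023 pandemic entrants total 11,397; plus the uniform +33% factor applied to 2019-2022 entry years in open-cohort plans.",
  "profile_2023": {
    "10-14": 1.4816571162623304,
    "15-19": 1.4816571162623304,
    "20-24": 1.4816571162623304,
    "25-29": 1.2889942697573982,
    "30-34": 1.2889942697573982,
    "35-39": 1.2889942697573982,
    "40-44": 1.2167457023180486,
    "45-49": 1.2167457023180486,
    "50-54": 1.2167457023180486,
    "55-59": 1.2167457023180486,
    "60-64": 1.2167457023180486,
    "65-69": 1.1204142790655827,
    "70-74": 1.1204142790655827,
    "75-79": 1.1204142790655827,
    "80-84": 1.1204142790655827,
    "85+": 1.1204142790655827
  },
  "uniform_2023": 1.25,
  "uplift_2019_2022": 1.33
}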