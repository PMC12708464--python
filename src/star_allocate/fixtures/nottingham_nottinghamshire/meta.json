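{
  "currency_label": "GBP",
  "extras": {
    "display_name": "Nottingham and Nottinghamshire ICS",
    "note": "Transcribed ranked pathway-improvement table from the published five-ICS STAR COPD analysis. population_copd is an indicative round number for context only; baseline interventions were not published in machine-readable form. consistency_flag marks rows whose printed cost/PHB ratio equals round(net_cost/phb_gain, 2); recommended_flag is a best-effort reading of the table highlighting as described in the accompanying narrative."
  },
  "name": "nottingham_nottinghamshire",
  "population_copd": 28500,
  "provenance": "fixture"
}
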