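{
  "$defs": {
    "ImprovementScenario": {
      "description": "One candidate pathway improvement under one scenario / uptake level.\n\nThe PHB gain is either supplied directly (``phb_gain``) or derived from\n``additional_treated / nnt * benefit_score``; if both are present they\nmust agree within 0.5%.  The net annual cost is either supplied\n(``net_cost``) or derived as ``implementation_cost - offset_savings``.\n\n``rank_printed``, ``cost_ratio_printed``, ``cost_phb_ratio_printed``,\n``recommended_flag`` and ``consistency_flag`` are transcription\nannotations carried by the packaged fixtures: ``consistency_flag`` is\nTrue when the published cost/PHB ratio is reproducible from the published\nnet cost and PHB gain at two-decimal rounding.  ``cost_ratio_printed``\nuses NaN for a published \"N/A\" and inf for a published \"\u221e\".",
      "properties": {
        "additional_treated": {
          "anyOf": [
            {
              "minimum": 0,
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Additional Treated"
        },
        "benefit_score": {
          "anyOf": [
            {
              "maximum": 100,
              "minimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Benefit Score"
        },
        "consistency_flag": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Consistency Flag"
        },
        "cost_phb_ratio_printed": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cost Phb Ratio Printed"
        },
        "cost_ratio_printed": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cost Ratio Printed"
        },
        "implementation_cost": {
          "anyOf": [
            {
              "minimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Implementation Cost"
        },
        "improvement_id": {
          "minLength": 1,
          "title": "Improvement Id",
          "type": "string"
        },
        "name": {
          "default": "",
          "title": "Name",
          "type": "string"
        },
        "net_cost": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Net Cost"
        },
        "nnt": {
          "anyOf": [
            {
              "minimum": 1,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Nnt"
        },
        "offset_savings": {
          "anyOf": [
            {
              "minimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Offset Savings"
        },
        "phb_gain": {
          "anyOf": [
            {
              "minimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Phb Gain"
        },
        "rank_printed": {
          "anyOf": [
            {
              "minimum": 1,
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Rank Printed"
        },
        "recommended_flag": {
          "default": false,
          "title": "Recommended Flag",
          "type": "boolean"
        },
        "scenario_label": {
          "default": "base",
          "title": "Scenario Label",
          "type": "string"
        }
      },
      "required": [
        "improvement_id"
      ],
      "title": "ImprovementScenario",
      "type": "object"
    },
    "InterventionRecord": {
      "description": "One baseline intervention in the current care pathway.",
      "properties": {
        "annual_cost": {
          "description": "currency units per year",
          "minimum": 0,
          "title": "Annual Cost",
          "type": "number"
        },
        "benefit_score": {
          "description": "VAS relative benefit",
          "maximum": 100,
          "minimum": 0,
          "title": "Benefit Score",
          "type": "number"
        },
        "id": {
          "minLength": 1,
          "title": "Id",
          "type": "string"
        },
        "n_treated": {
          "description": "people treated per year",
          "minimum": 0,
          "title": "N Treated",
          "type": "integer"
        },
        "name": {
          "default": "",
          "title": "Name",
          "type": "string"
        },
        "nnt": {
          "description": "number needed to treat",
          "minimum": 1,
          "title": "Nnt",
          "type": "number"
        },
        "segment": {
          "default": "",
          "title": "Segment",
          "type": "string"
        }
      },
      "required": [
        "id",
        "n_treated",
        "nnt",
        "benefit_score",
        "annual_cost"
      ],
      "title": "InterventionRecord",
      "type": "object"
    }
  },
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "description": "A named dataset: population context, pathway and improvement list.",
  "properties": {
    "currency_label": {
      "default": "GBP",
      "title": "Currency Label",
      "type": "string"
    },
    "extras": {
      "additionalProperties": true,
      "title": "Extras",
      "type": "object"
    },
    "improvements": {
      "items": {
        "$ref": "#/$defs/ImprovementScenario"
      },
      "title": "Improvements",
      "type": "array"
    },
    "interventions": {
      "items": {
        "$ref": "#/$defs/InterventionRecord"
      },
      "title": "Interventions",
      "type": "array"
    },
    "name": {
      "minLength": 1,
      "title": "Name",
      "type": "string"
    },
    "population_copd": {
      "exclusiveMinimum": 0,
      "title": "Population Copd",
      "type": "integer"
    },
    "provenance": {
      "default": "user",
      "enum": [
        "fixture",
        "synthetic",
        "user"
      ],
      "title": "Provenance",
      "type": "string"
    }
  },
  "required": [
    "name",
    "population_copd"
  ],
  "title": "ICSDataset",
  "type": "object"
}
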