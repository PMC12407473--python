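{
  "schema_version": "1.0",
  "title": "Workplace alcohol-reduction cluster-randomized trial",
  "solve_for": "power",
  "alpha": 0.05,
  "target_power": null,
  "between": {
    "factors": [
      {
        "name": "treatment",
        "levels": [
          "control",
          "training"
        ]
      }
    ],
    "allocation_ratios": [
      1,
      1
    ],
    "total_isus": 40
  },
  "within": {
    "outcomes": [
      {
        "name": "drinks_per_day",
        "sd": 1.1
      }
    ],
    "outcome_correlation": null,
    "repeated": null,
    "clusters": [
      {
        "name": "worker",
        "size": 15,
        "icc": 0.13
      }
    ]
  },
  "means": {
    "values": [
      [
        1.24
      ],
      [
        0.73
      ]
    ],
    "row_labels": [
      "treatment=control",
      "treatment=training"
    ],
    "column_labels": [
      "drinks_per_day"
    ]
  },
  "hypothesis": {
    "between": "treatment",
    "outcomes": "identity",
    "repeated": "average",
    "clusters": "average",
    "theta_null": null
  },
  "notes": null
}
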