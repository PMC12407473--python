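{
  "schema_version": "1.0",
  "title": "Sensory-focus longitudinal trial, memory of pain",
  "solve_for": "power",
  "alpha": 0.05,
  "target_power": 0.9,
  "between": {
    "factors": [
      {
        "name": "treatment",
        "levels": [
          "sensory_focus",
          "standard_of_care"
        ]
      }
    ],
    "allocation_ratios": [
      1,
      1
    ],
    "total_isus": 38
  },
  "within": {
    "outcomes": [
      {
        "name": "memory_of_pain",
        "sd": 0.9
      }
    ],
    "outcome_correlation": null,
    "repeated": {
      "timings": [
        0.0,
        6.0,
        12.0
      ],
      "structure": "unstructured",
      "correlation": [
        [
          1.0,
          0.5,
          0.4
        ],
        [
          0.5,
          1.0,
          0.5
        ],
        [
          0.4,
          0.5,
          1.0
        ]
      ],
      "rho": null,
      "rho_base": null,
      "delta_decay": null
    },
    "clusters": null
  },
  "means": {
    "values": [
      [
        3.6,
        2.8,
        0.9
      ],
      [
        4.5,
        4.3,
        3.0
      ]
    ],
    "row_labels": [
      "treatment=sensory_focus",
      "treatment=standard_of_care"
    ],
    "column_labels": [
      "memory_of_pain@t=0",
      "memory_of_pain@t=6",
      "memory_of_pain@t=12"
    ]
  },
  "hypothesis": {
    "between": "treatment",
    "outcomes": "identity",
    "repeated": "successive-difference",
    "clusters": "average",
    "theta_null": null
  },
  "notes": null
}
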