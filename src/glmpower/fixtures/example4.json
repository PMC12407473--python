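{
  "schema_version": "1.0",
  "title": "Adolescent alcohol-use multilevel longitudinal trial",
  "solve_for": "power",
  "alpha": 0.05,
  "target_power": 0.9,
  "between": {
    "factors": [
      {
        "name": "treatment",
        "levels": [
          "intervention",
          "standard_of_care"
        ]
      }
    ],
    "allocation_ratios": [
      2,
      1
    ],
    "total_isus": 102
  },
  "within": {
    "outcomes": [
      {
        "name": "alcohol_use",
        "sd": 4.0
      }
    ],
    "outcome_correlation": null,
    "repeated": {
      "timings": [
        0.0,
        1.0,
        3.0,
        5.0
      ],
      "structure": "lear",
      "correlation": null,
      "rho": null,
      "rho_base": 0.6,
      "delta_decay": 0.7
    },
    "clusters": [
      {
        "name": "student",
        "size": 20,
        "icc": 0.09
      },
      {
        "name": "classroom",
        "size": 3,
        "icc": 0.04
      },
      {
        "name": "school",
        "size": 2,
        "icc": 0.03
      }
    ]
  },
  "means": {
    "values": [
      [
        5.2,
        5.3,
        5.3,
        5.3
      ],
      [
        5.2,
        5.5,
        5.9,
        6.2
      ]
    ],
    "row_labels": [
      "treatment=intervention",
      "treatment=standard_of_care"
    ],
    "column_labels": [
      "alcohol_use@t=0",
      "alcohol_use@t=1",
      "alcohol_use@t=3",
      "alcohol_use@t=5"
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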