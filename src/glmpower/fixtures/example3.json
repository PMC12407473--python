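{
  "schema_version": "1.0",
  "title": "Early-literacy trial, multivariate scores, two-level clustering",
  "solve_for": "power",
  "alpha": 0.05,
  "target_power": null,
  "between": {
    "factors": [
      {
        "name": "program",
        "levels": [
          "intervention",
          "monolingual",
          "bilingual"
        ]
      }
    ],
    "allocation_ratios": [
      1,
      1,
      1
    ],
    "total_isus": 45
  },
  "within": {
    "outcomes": [
      {
        "name": "score_a",
        "sd": 4.4
      },
      {
        "name": "score_b",
        "sd": 4.2
      },
      {
        "name": "score_c",
        "sd": 0.6
      }
    ],
    "outcome_correlation": [
      [
        1.0,
        0.9,
        0.2
      ],
      [
        0.9,
        1.0,
        0.4
      ],
      [
        0.2,
        0.4,
        1.0
      ]
    ],
    "repeated": null,
    "clusters": [
      {
        "name": "student",
        "size": 5,
        "icc": 0.04
      },
      {
        "name": "classroom",
        "size": 4,
        "icc": 0.07
      }
    ]
  },
  "means": {
    "values": [
      [
        0.3,
        0.3,
        0.3
      ],
      [
        0.1,
        0.1,
        0.1
      ],
      [
        0.1,
        0.1,
        0.1
      ]
    ],
    "row_labels": [
      "program=intervention",
      "program=monolingual",
      "program=bilingual"
    ],
    "column_labels": [
      "score_a",
      "score_b",
      "score_c"
    ]
  },
  "hypothesis": {
    "between": "program",
    "outcomes": "identity",
    "repeated": "average",
    "clusters": "average",
    "theta_null": null
  },
  "notes": null
}
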