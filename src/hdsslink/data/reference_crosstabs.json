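{
  "description": "Published category counts of background characteristics in a fingerprint-matched gold-standard dataset (n=623) and in three record-linked subsets of it (scenarios S6, S16, S17). Used to validate the chi-squared distribution-comparison routine against the p-values published alongside these counts.",
  "gold": {
    "sex": {"Female": 511, "Male": 112},
    "age_group": {"18-34": 334, "35-49": 125, "50-64": 89, "65+": 75},
    "ethnicity": {"Other": 96, "South African": 527}
  },
  "matched": {
    "S6": {
      "sex": {"Female": 395, "Male": 97},
      "age_group": {"18-34": 284, "35-49": 100, "50-64": 66, "65+": 42},
      "ethnicity": {"Other": 67, "South African": 425}
    },
    "S16": {
      "sex": {"Female": 445, "Male": 106},
      "age_group": {"18-34": 308, "35-49": 112, "50-64": 78, "65+": 53},
      "ethnicity": {"Other": 76, "South African": 475}
    },
    "S17": {
      "sex": {"Female": 447, "Male": 105},
      "age_group": {"18-34": 308, "35-49": 115, "50-64": 77, "65+": 52},
      "ethnicity": {"Other": 75, "South African": 477}
    }
  },
  "published_p_values": {
    "S6": {"sex": 0.460, "age_group": 0.240, "ethnicity": 0.401},
    "S16": {"sex": 0.579, "age_group": 0.601, "ethnicity": 0.434},
    "S17": {"sex": 0.645, "age_group": 0.528, "ethnicity": 0.377}
  }
}
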