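{
  "description": "Published sex-stratified confusion matrices of the integrated Sasang constitutional diagnostic model (rows = true TE/SE/SY, columns = predicted TE/SE/SY). 'proposed' = the modified integrated model on its training/test split; 'cutoff' = the same predictions restricted to typical subjects by the margin cutoff; 'common' = the proposed vs the earlier fixed-weight model on the shared subset of test data. 'printed' blocks carry the percentages as published (1 decimal), used only to regression-test the evaluation arithmetic.",
  "common_samples": {"total": 1891, "male": 657, "female": 1234},
  "proposed": {
    "male": {
      "train": {"matrix": [[144, 14, 30], [14, 81, 26], [29, 28, 92]],
                "printed": {"sensitivity": {"TE": 76.6, "SE": 66.9, "SY": 61.7}, "accuracy": 69.2}},
      "test": {"matrix": [[64, 4, 8], [8, 35, 9], [22, 5, 44]],
               "printed": {"sensitivity": {"TE": 84.2, "SE": 67.3, "SY": 62.0}, "accuracy": 71.9}}
    },
    "female": {
      "train": {"matrix": [[223, 32, 66], [33, 146, 63], [65, 65, 168]],
                "printed": {"sensitivity": {"TE": 69.5, "SE": 60.3, "SY": 56.4}, "accuracy": 62.4}},
      "test": {"matrix": [[104, 12, 25], [12, 69, 26], [25, 28, 72]],
               "printed": {"sensitivity": {"TE": 73.8, "SE": 64.5, "SY": 57.6}, "accuracy": 65.7}}
    }
  },
  "cutoff": {
    "male": {
      "train": {"matrix": [[131, 9, 19], [10, 71, 17], [19, 15, 68]],
                "printed": {"sensitivity": {"TE": 82.4, "SE": 72.4, "SY": 66.7}, "accuracy": 75.2}},
      "test": {"matrix": [[58, 3, 3], [4, 29, 5], [15, 4, 38]],
               "printed": {"sensitivity": {"TE": 90.6, "SE": 76.3, "SY": 66.7}, "accuracy": 78.6}}
    },
    "female": {
      "train": {"matrix": [[181, 15, 39], [19, 110, 28], [39, 40, 114]],
                "printed": {"sensitivity": {"TE": 77.0, "SE": 70.1, "SY": 59.1}, "accuracy": 69.2}},
      "test": {"matrix": [[89, 11, 14], [8, 58, 9], [12, 14, 49]],
               "printed": {"sensitivity": {"TE": 78.1, "SE": 77.3, "SY": 65.3}, "accuracy": 74.2}}
    }
  },
  "common": {
    "proposed": {
      "male": {"matrix": [[36, 2, 5], [3, 21, 8], [14, 4, 24]],
               "printed": {"sensitivity": {"TE": 83.7, "SE": 65.6, "SY": 57.1}, "accuracy": 69.2}},
      "female": {"matrix": [[68, 9, 16], [7, 46, 15], [13, 21, 47]],
                 "printed": {"sensitivity": {"TE": 73.1, "SE": 67.6, "SY": 58.0}, "accuracy": 66.5}}
    },
    "previous": {
      "male": {"matrix": [[38, 3, 2], [9, 15, 8], [15, 7, 20]],
               "printed": {"sensitivity": {"TE": 88.4, "SE": 46.9, "SY": 47.6}, "accuracy": 62.4}},
      "female": {"matrix": [[62, 6, 25], [10, 27, 31], [18, 10, 53]],
                 "printed": {"sensitivity": {"TE": 66.7, "SE": 39.7, "SY": 65.4}, "accuracy": 58.7}}
    }
  }
}
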