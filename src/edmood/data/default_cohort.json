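{
  "seed": 1,
  "groups": [
    {
      "n": 609,
      "gad": [1.84, 1.45],
      "phq": [0.56, 0.83],
      "edeq": {
        "restraint": [2.32, 1.30],
        "eating_concern": [1.54, 0.79],
        "shape_concern": [2.11, 1.00],
        "weight_concern": [2.21, 1.30]
      },
      "binge": [2.75, 2.87],
      "vomit_mean": 0.04,
      "laxative_mean": 0.04,
      "exercise": [1.60, 1.28]
    },
    {
      "n": 567,
      "gad": [6.61, 1.32],
      "phq": [1.45, 1.17],
      "edeq": {
        "restraint": [2.63, 1.43],
        "eating_concern": [2.01, 1.09],
        "shape_concern": [2.67, 1.14],
        "weight_concern": [2.85, 1.47]
      },
      "binge": [3.58, 3.48],
      "vomit_mean": 0.10,
      "laxative_mean": 0.12,
      "exercise": [1.59, 1.09]
    },
    {
      "n": 371,
      "gad": [12.30, 1.69],
      "phq": [2.42, 1.15],
      "edeq": {
        "restraint": [2.97, 1.51],
        "eating_concern": [2.58, 1.46],
        "shape_concern": [3.23, 1.26],
        "weight_concern": [3.52, 1.66]
      },
      "binge": [4.76, 4.71],
      "vomit_mean": 0.20,
      "laxative_mean": 0.27,
      "exercise": [1.89, 1.42]
    },
    {
      "n": 245,
      "gad": [18.89, 1.92],
      "phq": [3.49, 1.63],
      "edeq": {
        "restraint": [3.30, 1.71],
        "eating_concern": [3.28, 1.78],
        "shape_concern": [3.73, 1.32],
        "weight_concern": [4.14, 1.79]
      },
      "binge": [5.08, 5.59],
      "vomit_mean": 0.30,
      "laxative_mean": 0.23,
      "exercise": [1.76, 1.30]
    }
  ],
  "intake": {
    "n_duplicates": 150,
    "n_incomplete": 405,
    "n_over_age": 81,
    "n_foreign_hs": 126,
    "n_graduate": 10
  }
}
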