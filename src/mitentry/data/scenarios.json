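{
  "narrow": {
    "distribution": "truncnorm",
    "mean": 4.0,
    "sd": 0.15,
    "n_cells": 400,
    "comment": "tight CDK2-cyclin A distribution: inhibition shifts a near-step entry curve"
  },
  "broad": {
    "distribution": "truncnorm",
    "mean": 4.0,
    "sd": 0.8,
    "n_cells": 400,
    "comment": "broad distribution: inhibition both delays and broadens entry times"
  },
  "broad_low_mean": {
    "distribution": "truncnorm",
    "mean": 2.6,
    "sd": 0.8,
    "n_cells": 400,
    "comment": "broad, lowered mean near the full-inhibition saddle-node: most cells fail to enter within 24 h at complete inhibition"
  }
}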