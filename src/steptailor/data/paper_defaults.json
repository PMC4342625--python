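{
 "arms": {
  "IG": {
   "n": 137,
   "step_means": [
    8759.98,
    9235.48,
    9483.86
   ],
   "step_sds": [
    3771.32,
    4281.05,
    4875.34
   ],
   "sitting_mean": 526.7,
   "sitting_sd": 163.7,
   "walking_means": [
    14.49,
    37.05,
    35.16
   ],
   "walking_sds": [
    22.86,
    92.52,
    52.49
   ],
   "moderate_means": [
    23.3,
    25.59,
    32.37
   ],
   "moderate_sds": [
    28.11,
    36.85,
    37.68
   ],
   "vigorous_means": [
    10.64,
    9.13,
    13.73
   ],
   "vigorous_sds": [
    17.8,
    15.2,
    21.58
   ],
   "retention": [
    0.7372262773722628,
    0.6642335766423357
   ]
  },
  "CG": {
   "n": 137,
   "step_means": [
    8627.69,
    8101.77,
    8589.15
   ],
   "step_sds": [
    3786.73,
    3882.31,
    4379.61
   ],
   "sitting_mean": 465.2,
   "sitting_sd": 186.1,
   "walking_means": [
    26.17,
    42.37,
    47.37
   ],
   "walking_sds": [
    51.93,
    86.66,
    72.6
   ],
   "moderate_means": [
    24.94,
    15.43,
    38.44
   ],
   "moderate_sds": [
    36.21,
    20.08,
    60.04
   ],
   "vigorous_means": [
    9.76,
    6.78,
    10.69
   ],
   "vigorous_sds": [
    23.1,
    13.48,
    18.44
   ],
   "retention": [
    0.8175182481751825,
    0.781021897810219
   ]
  }
 },
 "clusters": [
  {
   "label": "school_a",
   "kind": "school",
   "arm": "IG",
   "size": 35
  },
  {
   "label": "school_b",
   "kind": "school",
   "arm": "IG",
   "size": 34
  },
  {
   "label": "commercial_a",
   "kind": "commercial",
   "arm": "IG",
   "size": 34
  },
  {
   "label": "nonprofit_a",
   "kind": "nonprofit",
   "arm": "IG",
   "size": 34
  },
  {
   "label": "school_c",
   "kind": "school",
   "arm": "CG",
   "size": 35
  },
  {
   "label": "commercial_b",
   "kind": "commercial",
   "arm": "CG",
   "size": 34
  },
  {
   "label": "commercial_c",
   "kind": "commercial",
   "arm": "CG",
   "size": 34
  },
  {
   "label": "nonprofit_b",
   "kind": "nonprofit",
   "arm": "CG",
   "size": 34
  }
 ],
 "rho": 0.6,
 "cluster_sd": 0.0,
 "selfreport_bias": 1.0,
 "commercial_dropout_multiplier": 1.0,
 "truncation_cap": 20000.0
}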