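{
 "letters": [
  {
   "id": "A",
   "class": "helix",
   "coords": [
    [
     -2.2067,
     -1.8725,
     0.7276
    ],
    [
     1.5933,
     -1.8725,
     0.7276
    ],
    [
     1.527,
     1.9269,
     0.7276
    ],
    [
     -0.9137,
     1.818,
     -2.1829
    ]
   ]
  },
  {
   "id": "B",
   "class": "helix",
   "coords": [
    [
     -2.0127,
     -1.8673,
     0.6713
    ],
    [
     1.7873,
     -1.8673,
     0.6713
    ],
    [
     1.4561,
     1.9183,
     0.6713
    ],
    [
     -1.2306,
     1.8163,
     -2.014
    ]
   ]
  },
  {
   "id": "C",
   "class": "helix",
   "coords": [
    [
     -2.4031,
     -1.8597,
     0.7763
    ],
    [
     1.3969,
     -1.8597,
     0.7763
    ],
    [
     1.5957,
     1.9351,
     0.7763
    ],
    [
     -0.5894,
     1.7842,
     -2.3289
    ]
   ]
  },
  {
   "id": "D",
   "class": "helix",
   "coords": [
    [
     -2.0905,
     -1.9698,
     0.6083
    ],
    [
     1.7095,
     -1.9698,
     0.6083
    ],
    [
     1.6431,
     1.8296,
     0.6083
    ],
    [
     -1.2621,
     2.1101,
     -1.825
    ]
   ]
  },
  {
   "id": "E",
   "class": "helix",
   "coords": [
    [
     -2.541,
     -1.9176,
     0.8226
    ],
    [
     1.259,
     -1.9176,
     0.8226
    ],
    [
     1.5902,
     1.8679,
     0.8226
    ],
    [
     -0.3081,
     1.9674,
     -2.4678
    ]
   ]
  },
  {
   "id": "F",
   "class": "helix",
   "coords": [
    [
     -2.6597,
     -2.0469,
     0.7752
    ],
    [
     1.1403,
     -2.0469,
     0.7752
    ],
    [
     1.8001,
     1.6953,
     0.7752
    ],
    [
     -0.2807,
     2.3985,
     -2.3257
    ]
   ]
  },
  {
   "id": "G",
   "class": "sheet",
   "coords": [
    [
     -4.7392,
     -1.6517,
     -0.1429
    ],
    [
     -0.9392,
     -1.6517,
     -0.1429
    ],
    [
     0.9608,
     1.6392,
     -0.1429
    ],
    [
     4.7175,
     1.6642,
     0.4286
    ]
   ]
  },
  {
   "id": "H",
   "class": "sheet",
   "coords": [
    [
     -4.8801,
     -1.4424,
     -0.0731
    ],
    [
     -1.0801,
     -1.4424,
     -0.0731
    ],
    [
     1.0995,
     1.6703,
     -0.0731
    ],
    [
     4.8607,
     1.2146,
     0.2193
    ]
   ]
  },
  {
   "id": "I",
   "class": "sheet",
   "coords": [
    [
     -4.5482,
     -1.8907,
     -0.2694
    ],
    [
     -0.7482,
     -1.8907,
     -0.2694
    ],
    [
     0.8577,
     1.5533,
     -0.2694
    ],
    [
     4.4387,
     2.228,
     0.8081
    ]
   ]
  },
  {
   "id": "J",
   "class": "sheet",
   "coords": [
    [
     -5.0204,
     -1.4226,
     0.0261
    ],
    [
     -1.2204,
     -1.4226,
     0.0261
    ],
    [
     1.2222,
     1.4883,
     0.0261
    ],
    [
     5.0185,
     1.3569,
     -0.0784
    ]
   ]
  },
  {
   "id": "K",
   "class": "sheet",
   "coords": [
    [
     -4.6573,
     -1.5307,
     -0.5052
    ],
    [
     -0.8573,
     -1.5307,
     -0.5052
    ],
    [
     1.1564,
     1.6918,
     -0.5052
    ],
    [
     4.3583,
     1.3696,
     1.5157
    ]
   ]
  },
  {
   "id": "L",
   "class": "sheet",
   "coords": [
    [
     -4.6493,
     -1.8868,
     0.1884
    ],
    [
     -0.8493,
     -1.8868,
     0.1884
    ],
    [
     0.9347,
     1.4684,
     0.1884
    ],
    [
     4.564,
     2.3051,
     -0.5651
    ]
   ]
  },
  {
   "id": "M",
   "class": "loop",
   "coords": [
    [
     -4.0304,
     -1.9381,
     -0.7731
    ],
    [
     -0.2304,
     -1.9381,
     -0.7731
    ],
    [
     1.0693,
     1.6328,
     -0.7731
    ],
    [
     3.1915,
     2.2434,
     2.3193
    ]
   ]
  },
  {
   "id": "N",
   "class": "loop",
   "coords": [
    [
     -3.1217,
     -2.3637,
     -0.8102
    ],
    [
     0.6783,
     -2.3637,
     -0.8102
    ],
    [
     1.3381,
     1.3785,
     -0.8102
    ],
    [
     1.1053,
     3.3489,
     2.4307
    ]
   ]
  },
  {
   "id": "O",
   "class": "loop",
   "coords": [
    [
     -3.4774,
     -2.0222,
     -0.8102
    ],
    [
     0.3226,
     -2.0222,
     -0.8102
    ],
    [
     2.2226,
     1.2687,
     -0.8102
    ],
    [
     0.9321,
     2.7757,
     2.4307
    ]
   ]
  },
  {
   "id": "P",
   "class": "loop",
   "coords": [
    [
     -2.2737,
     -2.2838,
     -0.4464
    ],
    [
     1.5263,
     -2.2838,
     -0.4464
    ],
    [
     1.8574,
     1.5017,
     -0.4464
    ],
    [
     -1.1099,
     3.066,
     1.3391
    ]
   ]
  },
  {
   "id": "Q",
   "class": "loop",
   "coords": [
    [
     -2.6388,
     -2.1869,
     0.0
    ],
    [
     1.1612,
     -2.1869,
     0.0
    ],
    [
     2.4608,
     1.3839,
     0.0
    ],
    [
     -0.9831,
     2.9899,
     0.0
    ]
   ]
  },
  {
   "id": "R",
   "class": "loop",
   "coords": [
    [
     -2.6378,
     -2.2784,
     0.4588
    ],
    [
     1.1622,
     -2.2784,
     0.4588
    ],
    [
     2.1457,
     1.3921,
     0.4588
    ],
    [
     -0.6702,
     3.1648,
     -1.3764
    ]
   ]
  },
  {
   "id": "S",
   "class": "loop",
   "coords": [
    [
     -2.85,
     -2.375,
     0.8227
    ],
    [
     0.95,
     -2.375,
     0.8227
    ],
    [
     0.95,
     1.425,
     0.8227
    ],
    [
     0.95,
     3.325,
     -2.4682
    ]
   ]
  },
  {
   "id": "T",
   "class": "loop",
   "coords": [
    [
     -4.2114,
     -1.4079,
     0.8227
    ],
    [
     -0.4114,
     -1.4079,
     0.8227
    ],
    [
     1.4886,
     1.8829,
     0.8227
    ],
    [
     3.1341,
     0.9329,
     -2.4682
    ]
   ]
  },
  {
   "id": "U",
   "class": "loop",
   "coords": [
    [
     -4.0065,
     -1.8929,
     0.4678
    ],
    [
     -0.2065,
     -1.8929,
     0.4678
    ],
    [
     0.4534,
     1.8494,
     0.4678
    ],
    [
     3.7596,
     1.9364,
     -1.4034
    ]
   ]
  },
  {
   "id": "V",
   "class": "loop",
   "coords": [
    [
     -4.2504,
     -1.4133,
     -0.932
    ],
    [
     -0.4504,
     -1.4133,
     -0.932
    ],
    [
     1.9922,
     1.4977,
     -0.932
    ],
    [
     2.7086,
     1.3289,
     2.796
    ]
   ]
  },
  {
   "id": "W",
   "class": "loop",
   "coords": [
    [
     -2.8812,
     -2.5175,
     0.7029
    ],
    [
     0.9188,
     -2.5175,
     0.7029
    ],
    [
     1.25,
     1.268,
     0.7029
    ],
    [
     0.7123,
     3.767,
     -2.1088
    ]
   ]
  },
  {
   "id": "X",
   "class": "loop",
   "coords": [
    [
     -3.2559,
     -2.3458,
     -0.6088
    ],
    [
     0.5441,
     -2.3458,
     -0.6088
    ],
    [
     0.2129,
     1.4397,
     -0.6088
    ],
    [
     2.4989,
     3.2518,
     1.8264
    ]
   ]
  },
  {
   "id": "Y",
   "class": "loop",
   "coords": [
    [
     -3.84,
     -1.5434,
     0.9141
    ],
    [
     -0.04,
     -1.5434,
     0.9141
    ],
    [
     1.566,
     1.9005,
     0.9141
    ],
    [
     2.314,
     1.1863,
     -2.7424
    ]
   ]
  }
 ]
}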