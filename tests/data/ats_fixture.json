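{
  "y": [
    [1, 3, 2],
    [4, 4, 5],
    [2, 6, 3],
    [5, 2, 4],
    [3, 5, 7],
    [6, 8, 6],
    [7, 7, 9],
    [8, 9, 8]
  ],
  "groups": ["A", "A", "A", "A", "B", "B", "B", "B"],
  "relative_effects": [
    [0.23958333333333334, 0.32291666666666669, 0.29166666666666669],
    [0.60416666666666663, 0.75520833333333337, 0.78645833333333337]
  ],
  "group": {
    "statistic": 16.29964664310954,
    "df": 1.0000000000000002,
    "p": 5.4074034050480721e-05,
    "df_den_box": 5.2099984994531248,
    "p_box": 0.0091417431159231313
  },
  "condition": {
    "statistic": 1.2225799959750474,
    "df": 1.7089498908190328,
    "p": 0.2904580623821032
  },
  "interaction": {
    "statistic": 0.28315556449989943,
    "df": 1.7089498908190328,
    "p": 0.71832097665339556
  }
}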