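[
  {"structure": "CTV", "goal": "D0.03cc < 105% (109%)"},
  {"structure": "CTV", "goal": "D95% > 100%"},
  {"structure": "CTV", "goal": "V60Gy > 95% (93%)"},
  {"structure": "PTV", "goal": "D0.03cc < 105% (109%)"},
  {"structure": "PTV", "goal": "D95% > 100%"},
  {"structure": "PTV", "goal": "V60Gy > 95% (93%)"},
  {"structure": "rectum", "goal": "D0.03cc < 62.4Gy (64.2Gy)"},
  {"structure": "rectum", "goal": "V60Gy < 3% (10%)"},
  {"structure": "rectum", "goal": "V57Gy < 10% (15%)"},
  {"structure": "rectum", "goal": "V52.8Gy < 20% (30%)"},
  {"structure": "rectum", "goal": "V50Gy < 22% (30%)"},
  {"structure": "rectum", "goal": "V48.6Gy < 30% (50%)"},
  {"structure": "rectum", "goal": "V40.8Gy < 35% (60%)"},
  {"structure": "rectum", "goal": "V40Gy < 38% (45%)"},
  {"structure": "rectum", "goal": "V30Gy < 57% (65%)"},
  {"structure": "rectum", "goal": "V20Gy < 85% (90%)"},
  {"structure": "bladder", "goal": "D0.03cc < 62.4Gy"},
  {"structure": "bladder", "goal": "V60Gy < 5% (10%)"},
  {"structure": "bladder", "goal": "V48.6Gy < 20% (25%)"},
  {"structure": "bladder", "goal": "V40.8Gy < 35% (50%)"},
  {"structure": "femur_L", "goal": "V40.8Gy < 45% (50%)"},
  {"structure": "femur_R", "goal": "V40.8Gy < 45% (50%)"}
]
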