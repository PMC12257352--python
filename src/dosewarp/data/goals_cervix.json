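[
  {"structure": "CTV", "goal": "D0.03cc < 105%"},
  {"structure": "CTV", "goal": "D95% > 100%"},
  {"structure": "CTV", "goal": "D97% > 99%"},
  {"structure": "CTV", "goal": "V45Gy > 95%"},
  {"structure": "PTV", "goal": "D0.03cc < 105%"},
  {"structure": "PTV", "goal": "D95% > 100%"},
  {"structure": "PTV", "goal": "D97% > 99%"},
  {"structure": "PTV", "goal": "V45Gy > 95%"},
  {"structure": "rectum", "goal": "D0.03cc < 47.25Gy"},
  {"structure": "rectum", "goal": "V40Gy < 50%"},
  {"structure": "bladder", "goal": "D0.03cc < 47.25Gy"},
  {"structure": "bladder", "goal": "V40Gy < 50%"},
  {"structure": "bowel_bag", "goal": "D0.03cc < 47.25Gy"},
  {"structure": "bowel", "goal": "D0.03cc < 47.25Gy"},
  {"structure": "bowel_minus_ctv", "goal": "D0.03cc < 47.25Gy"},
  {"structure": "bowel_minus_ctv", "goal": "V45Gy < 50cc"},
  {"structure": "bowel_minus_ctv", "goal": "V40Gy < 100cc"},
  {"structure": "femur_L", "goal": "D0.03cc < 47.25Gy"},
  {"structure": "femur_L", "goal": "V30Gy < 15%"},
  {"structure": "femur_R", "goal": "D0.03cc < 47.25Gy"},
  {"structure": "femur_R", "goal": "V30Gy < 15%"}
]
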