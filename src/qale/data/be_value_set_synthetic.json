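{
  "name": "belgium-synthetic",
  "comment": "SYNTHETIC stand-in for the Belgian EQ-5D-5L value set. Additive main-effects decrements calibrated so that state 11111 scores 1, 11113 scores 0.849, 11333 scores 0.678 and 55555 scores -0.532 (the published example utilities of the Belgian set); the remaining decrements are plausible magnitudes, not the published ones. Do not use for real valuation work.",
  "decrements": {
    "mobility":           [0.0, 0.04, 0.07, 0.22, 0.27],
    "self_care":          [0.0, 0.04, 0.08, 0.19, 0.24],
    "usual_activities":   [0.0, 0.04, 0.08, 0.20, 0.26],
    "pain_discomfort":    [0.0, 0.05, 0.091, 0.27, 0.35],
    "anxiety_depression": [0.0, 0.06, 0.151, 0.32, 0.412]
  }
}
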