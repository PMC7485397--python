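{
  "modality": "swe",
  "selected_indices": [518, 532, 565, 719],
  "coefficients": [-0.3666784, -1.43192, -0.4749501, -0.2671713],
  "intercept": 2.496014,
  "threshold": -0.24,
  "lambda_": null,
  "orientation": "lower_is_malignant",
  "standardized": false,
  "feature_means": null,
  "feature_scales": null,
  "seed": null,
  "notes": "Frozen published reference SWE rad-score formula over the 768-dim deep feature vector; orientation relative to the printed threshold is an assumption (all coefficients are negative). Used for scoring-arithmetic validation only."
}
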